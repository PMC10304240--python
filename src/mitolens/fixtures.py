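"""Deterministic fixture models and stacks for testing and validation.

Every fixture is generated from code — no external data:

* ``flat_wall``       — the 25-medium wall as an infinite slab, for
  spectral checks against the stack optics.
* ``null_sphere``     — index-matched sphere (all 1.33), no membranes:
  light must pass untouched.
* ``ball_lens``       — homogeneous sphere at the wall's
  thickness-weighted mean index (~1.43) in cytosol, no membranes.
* ``reference_wall``  — the 12-bilayer/11-gap stack itself.
"""

from __future__ import annotations

from .bilayer import reference_wall as _reference_wall
from .geometry import MitochondrionModel, build_mitochondrion
from .stratified import StratifiedStack

__all__ = ["FIXTURE_NAMES", "make_fixture"]

FIXTURE_NAMES = ("flat_wall", "null_sphere", "ball_lens", "reference_wall")


def make_fixture(name: str) -> MitochondrionModel | StratifiedStack:
    """Build a named fixture model or stack; raises on unknown names."""
    if name == "flat_wall":
        return _reference_wall()
    if name == "reference_wall":
        return _reference_wall()
    if name == "null_sphere":
        return build_mitochondrion(n_A=1.33, n_B=1.33, n_exterior=1.33, wall_stack=None)
    if name == "ball_lens":
        wall = _reference_wall()
        return build_mitochondrion(
            n_A=wall.mean_index, n_B=wall.mean_index, n_exterior=1.33, wall_stack=None
        )
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
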