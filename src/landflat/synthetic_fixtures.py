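"""Deterministic toy design systems with enumerable ground truth.

Real energy matrices come from force-field calculations on crystal
structures and are opaque inputs here.  For testing every pipeline stage
end to end, this module generates small paired-state matrices whose exact
sequence thermodynamics can be enumerated by :mod:`landflat.exact_oracle`:

- random diagonal energies at a chosen scale (zero-mean normal),
- sparse random pair terms (included with probability ``pair_density``),
- a *holo* state equal to the *apo* state plus a perturbation, and
- optional *planted binders*: sequences whose enumerated relative binding
  free energy is pinned to a requested value exactly.

Planting works by adding a constant to the holo diagonal entries of the
planted sequence's type at a dedicated *marker position* (the first
position).  A constant added to every microstate of that marker type
shifts the sequence free energy by exactly that constant, so the residual
between the current and the requested ddG (measured at ``spec.kT``) can be
cancelled to machine precision.  Planted sequences must therefore carry
distinct marker types, all different from the reference sequence's.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .energy_model import AMINO_ACIDS, EnergyMatrix, SequenceSpace
from .exact_oracle import exact_ddG

__all__ = ["FixtureSpec", "generate_space", "generate_pair", "generate_triple"]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a toy design system.

    Defaults give a 3-position, 5-type, 2-rotamer space (1000 microstates,
    125 sequences) with kcal/mol-scale ruggedness — small enough for the
    exact oracle to enumerate in milliseconds, rich enough to exercise
    flattening and the two-stage free-energy pipeline.
    """

    n_positions: int = 3
    types_per_position: int = 5
    rotamers_per_type: int = 2
    energy_scale: float = 1.0  # kcal/mol, sd of diagonal terms
    pair_density: float = 0.25
    planted_binders: tuple = ()  # (sequence, ddG_bind[, ddG_act]) tuples
    seed: int = 0
    kT: float = 0.59  # thermal energy at which planted values are exact
    n_flexible: int = 0  # extra rotamer-only positions

    def __post_init__(self):
        if not 1 <= self.types_per_position <= 20:
            raise ValueError("types_per_position must be in 1..20")
        if min(self.n_positions, self.rotamers_per_type) < 1:
            raise ValueError("need >= 1 position and rotamer")
        if not 0.0 <= self.pair_density <= 1.0:
            raise ValueError("pair_density must lie in [0, 1]")
        object.__setattr__(
            self, "planted_binders", tuple(tuple(p) for p in self.planted_binders)
        )

    def replace(self, **kw) -> "FixtureSpec":
        return dataclasses.replace(self, **kw)

    @property
    def reference(self) -> str:
        """Reference sequence: the first allowed type at every position."""
        return AMINO_ACIDS[0] * self.n_positions

    def manifest(self) -> dict:
        return {
            "spec": dataclasses.asdict(self),
            "reference": self.reference,
            "planted": [list(p) for p in self.planted_binders],
        }


def generate_space(spec: FixtureSpec) -> SequenceSpace:
    types = AMINO_ACIDS[: spec.types_per_position]
    flexible = {
        1000 + k: ("W", spec.rotamers_per_type) for k in range(spec.n_flexible)
    }
    return SequenceSpace(
        positions=range(1, spec.n_positions + 1),
        allowed_types=[types] * spec.n_positions,
        rotamer_counts=spec.rotamers_per_type,
        flexible=flexible,
    )


def _random_matrix(space: SequenceSpace, label, rng, scale, pair_density):
    m = EnergyMatrix(space, label)
    for pos in space.all_positions:
        for t in space.types_at(pos):
            for r in range(space.rotamers_at(pos, t)):
                m.set_diag(pos, t, r, rng.normal(0.0, scale) if scale > 0 else 0.0)
    positions = space.all_positions
    for a, i in enumerate(positions):
        for j in positions[a + 1:]:
            for ti in space.types_at(i):
                for ri in range(space.rotamers_at(i, ti)):
                    for tj in space.types_at(j):
                        for rj in range(space.rotamers_at(j, tj)):
                            if rng.random() < pair_density and scale > 0:
                                m.set_pair(
                                    i, ti, ri, j, tj, rj,
                                    rng.normal(0.0, 0.5 * scale),
                                )
    return m


def _perturb(matrix: EnergyMatrix, label, rng, scale) -> EnergyMatrix:
    """A correlated second state: same topology, diagonal and existing pair
    terms jittered at half the base scale."""
    m = matrix.copy()
    m.state_label = label
    for key in m.diag:
        m.diag[key] += rng.normal(0.0, 0.5 * scale) if scale > 0 else 0.0
    for key in m.pair:
        m.pair[key] += rng.normal(0.0, 0.25 * scale) if scale > 0 else 0.0
    return m


def _plant(bound: EnergyMatrix, free: EnergyMatrix, spec: FixtureSpec, targets):
    """Pin exact_ddG(bound vs free) for the target sequences by shifting
    the bound-state diagonal of each sequence's marker type."""
    if not targets:
        return
    space = bound.space
    marker = space.positions[0]
    ref = spec.reference
    seen = {ref[0]}
    for seq, _ in targets:
        if not space.contains_sequence(seq):
            raise ValueError(f"planted sequence {seq!r} outside the space")
        if seq[0] in seen:
            raise ValueError(
                "planted sequences need distinct marker types (position 1) "
                "different from the reference"
            )
        seen.add(seq[0])
    current = exact_ddG(free, bound, spec.kT, ref)
    for seq, target in targets:
        shift = float(target) - current[seq]
        t = seq[0]
        for r in range(space.rotamers_at(marker, t)):
            bound.set_diag(marker, t, r, bound.diag_energy(marker, t, r) + shift)


def generate_pair(spec: FixtureSpec):
    """(apo, holo) matrices; holo = apo + perturbation, then planted-binder
    corrections so enumerated ddG matches each target at ``spec.kT``."""
    rng = np.random.default_rng(spec.seed)
    space = generate_space(spec)
    apo = _random_matrix(space, "apo", rng, spec.energy_scale, spec.pair_density)
    holo = _perturb(apo, "holo", rng, spec.energy_scale)
    _plant(holo, apo, spec, [(p[0], p[1]) for p in spec.planted_binders])
    return apo, holo


def generate_triple(spec: FixtureSpec):
    """(ground, transition, unbound) matrices for the catalytic-power
    pipeline.

    ``unbound`` is the enzyme with no substrate; ``ground`` the substrate
    complex (planted ddG_bind vs unbound); ``transition`` the activated
    complex (planted ddG_act vs ground).  Planted entries use the 2- or
    3-field form ``(sequence, ddG_bind[, ddG_act])`` of
    ``spec.planted_binders``.
    """
    rng = np.random.default_rng(spec.seed)
    space = generate_space(spec)
    unbound = _random_matrix(space, "unbound", rng, spec.energy_scale, spec.pair_density)
    ground = _perturb(unbound, "ground", rng, spec.energy_scale)
    transition = _perturb(ground, "transition", rng, spec.energy_scale)
    binds = [(p[0], p[1]) for p in spec.planted_binders]
    acts = [(p[0], p[2] if len(p) > 2 else 0.0) for p in spec.planted_binders]
    _plant(ground, unbound, spec, binds)
    _plant(transition, ground, spec, acts)
    return ground, transition, unbound


def write_fixture(spec: FixtureSpec, outdir, kind: str = "pair") -> dict:
    """Write fixture matrices plus a JSON manifest; returns the manifest."""
    import os

    os.makedirs(outdir, exist_ok=True)
    manifest = spec.manifest()
    if kind == "pair":
        apo, holo = generate_pair(spec)
        names = {"apo": apo, "holo": holo}
    elif kind == "triple":
        ground, transition, unbound = generate_triple(spec)
        names = {"ground": ground, "transition": transition, "unbound": unbound}
    else:
        raise ValueError("kind must be 'pair' or 'triple'")
    manifest["kind"] = kind
    manifest["files"] = {}
    for name, m in names.items():
        path = os.path.join(outdir, f"{name}.mat")
        m.save(path)
        manifest["files"][name] = path
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
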