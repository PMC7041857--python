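"""Well-tempered adaptive bias over sequence space.

The bias is a sum of per-position (and optionally per-position-pair)
penalties over residue *types* — never rotamers::

    E_B(s_1..s_p) = sum_i E_i(s_i) + sum_{i<j} E_ij(s_i, s_j)

During a flattening run the currently occupied sequence is penalized every
``update_period`` MC steps by an increment that decays exponentially with
the bias already accumulated on that term::

    e_i(s) = e0 * exp(-E_i(s) / E0)

so that adaptation is aggressive early (Wang-Landau-like when E0 is large)
and self-limiting later (well-tempered).  Once the landscape of the
reference state is flat, the bias approximates the negative of that
state's sequence free energy up to a constant, which is what makes the
second-stage sampling proportional to relative binding free energies.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy_model import EnergyMatrix, SequenceSpace

__all__ = [
    "BiasPotential",
    "bias_energy",
    "increment",
    "update_bias",
    "run_flattening",
    "flatness_report",
    "FlatnessReport",
]


class BiasPotential:
    """Single-position (and optional pair) bias terms over residue types.

    Parameters use the published defaults: increment scale ``e0 = 0.2``
    kcal/mol, tempering energy ``E0 = 50`` kcal/mol, updates every
    ``update_period = 1000`` MC steps.  Terms start at zero and only ever
    grow (increments are positive).
    """

    def __init__(
        self,
        space: SequenceSpace,
        e0: float = 0.2,
        E0: float = 50.0,
        update_period: int = 1000,
        pair_terms: bool = False,
    ):
        if e0 <= 0 or E0 <= 0:
            raise ValueError("e0 and E0 must be positive")
        if update_period < 1:
            raise ValueError("update_period must be >= 1")
        self.space = space
        self.e0 = float(e0)
        self.E0 = float(E0)
        self.update_period = int(update_period)
        self.pair_enabled = bool(pair_terms)
        n = len(space.positions)
        tmax = max((len(ts) for ts in space.allowed_types), default=1)
        self._single = np.zeros((n, tmax))
        self._pair = np.zeros((n, n, tmax, tmax)) if pair_terms else np.zeros((1, 1, 1, 1))

    # -- indexing ----------------------------------------------------------
    def _ti(self, k: int, t: str) -> int:
        try:
            return self.space.allowed_types[k].index(t)
        except ValueError:
            raise KeyError(
                f"type {t!r} not allowed at position {self.space.positions[k]}"
            ) from None

    def _pi(self, pos: int) -> int:
        try:
            return self.space.positions.index(pos)
        except ValueError:
            raise KeyError(f"{pos} is not a mutable position") from None

    def single_term(self, pos: int, t: str) -> float:
        k = self._pi(pos)
        return float(self._single[k, self._ti(k, t)])

    def pair_term(self, i: int, j: int, ti: str, tj: str) -> float:
        if not self.pair_enabled:
            return 0.0
        a, b = self._pi(i), self._pi(j)
        if a > b:
            a, b, ti, tj = b, a, tj, ti
        return float(self._pair[a, b, self._ti(a, ti), self._ti(b, tj)])

    # -- spec operations ---------------------------------------------------
    def bias_energy(self, sequence: str) -> float:
        """Total bias of a sequence (types at the mutable positions)."""
        p = len(self.space.positions)
        if len(sequence) != p:
            raise ValueError("sequence length does not match mutable positions")
        idx = [self._ti(k, t) for k, t in enumerate(sequence)]
        e = sum(self._single[k, idx[k]] for k in range(p))
        if self.pair_enabled:
            for a in range(p):
                for b in range(a + 1, p):
                    e += self._pair[a, b, idx[a], idx[b]]
        return float(e)

    def increment(self, *key) -> float:
        """Well-tempered increment for a single (pos, type) or pair
        (i, j, type_i, type_j) term: ``e0 * exp(-current / E0)``."""
        if len(key) == 2:
            current = self.single_term(*key)
        elif len(key) == 4:
            current = self.pair_term(*key)
        else:
            raise TypeError("increment takes (pos, type) or (i, j, type, type)")
        return self.e0 * float(np.exp(-current / self.E0))

    def update(self, sequence: str) -> None:
        """Penalize the currently occupied sequence.

        Every single term addressed by the sequence gains its increment;
        when pair terms are enabled, every (i<j) pair term does too.  All
        increments are computed from the pre-update values.
        """
        p = len(self.space.positions)
        if len(sequence) != p:
            raise ValueError("sequence length does not match mutable positions")
        idx = [self._ti(k, t) for k, t in enumerate(sequence)]
        incs = [self.e0 * np.exp(-self._single[k, idx[k]] / self.E0) for k in range(p)]
        pair_incs = []
        if self.pair_enabled:
            for a in range(p):
                for b in range(a + 1, p):
                    pair_incs.append(
                        (a, b, self.e0 * np.exp(-self._pair[a, b, idx[a], idx[b]] / self.E0))
                    )
        for k in range(p):
            self._single[k, idx[k]] += incs[k]
        for a, b, inc in pair_incs:
            self._pair[a, b, idx[a], idx[b]] += inc

    # -- utilities ---------------------------------------------------------
    def copy(self) -> "BiasPotential":
        b = BiasPotential(
            self.space, self.e0, self.E0, self.update_period, self.pair_enabled
        )
        b._single = self._single.copy()
        b._pair = self._pair.copy()
        return b

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self._single.tobytes())
        h.update(self._pair.tobytes())
        return h.hexdigest()[:12]

    def save(self, path) -> None:
        space = self.space
        lines = [
            "# landflat bias potential",
            f"E0 {self.E0:.12g}",
            f"e0 {self.e0:.12g}",
            f"UPDATE_PERIOD {self.update_period}",
            f"PAIR_TERMS {'on' if self.pair_enabled else 'off'}",
        ]
        for p, ts in zip(space.positions, space.allowed_types):
            lines.append(f"POSITION {p} {''.join(ts)}")
        for k, (p, ts) in enumerate(zip(space.positions, space.allowed_types)):
            for a, t in enumerate(ts):
                lines.append(f"SINGLE {p} {t} {self._single[k, a]:.17g}")
        if self.pair_enabled:
            for a, (pi, tsi) in enumerate(zip(space.positions, space.allowed_types)):
                for b in range(a + 1, len(space.positions)):
                    pj, tsj = space.positions[b], space.allowed_types[b]
                    for x, ti in enumerate(tsi):
                        for y, tj in enumerate(tsj):
                            v = self._pair[a, b, x, y]
                            if v != 0.0:
                                lines.append(f"PAIR {pi} {pj} {ti} {tj} {v:.17g}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path, space: SequenceSpace | None = None) -> "BiasPotential":
        params = {"e0": 0.2, "E0": 50.0, "update_period": 1000, "pair": False}
        positions, types = [], []
        singles, pairs = [], []
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                f = line.split()
                tag = f[0]  # e0 / E0 are case-sensitive tags
                if tag == "E0":
                    params["E0"] = float(f[1])
                elif tag == "e0":
                    params["e0"] = float(f[1])
                elif tag == "UPDATE_PERIOD":
                    params["update_period"] = int(f[1])
                elif tag == "PAIR_TERMS":
                    params["pair"] = f[1].lower() == "on"
                elif tag == "POSITION":
                    positions.append(int(f[1]))
                    types.append(list(f[2]))
                elif tag == "SINGLE":
                    singles.append((int(f[1]), f[2], float(f[3])))
                elif tag == "PAIR":
                    pairs.append((int(f[1]), int(f[2]), f[3], f[4], float(f[5])))
                else:
                    raise ValueError(f"unknown bias record {f[0]!r}")
        if space is None:
            space = SequenceSpace(positions, types, 1)
        bias = cls(
            space,
            e0=params["e0"],
            E0=params["E0"],
            update_period=params["update_period"],
            pair_terms=params["pair"],
        )
        for pos, t, v in singles:
            k = bias._pi(pos)
            bias._single[k, bias._ti(k, t)] = v
        for i, j, ti, tj, v in pairs:
            a, b = bias._pi(i), bias._pi(j)
            if a > b:
                a, b, ti, tj = b, a, tj, ti
            bias._pair[a, b, bias._ti(a, ti), bias._ti(b, tj)] = v
        return bias


# -- module-level spec surface ---------------------------------------------

def bias_energy(bias: BiasPotential, sequence: str) -> float:
    return bias.bias_energy(sequence)


def increment(bias: BiasPotential, *key) -> float:
    return bias.increment(*key)


def update_bias(bias: BiasPotential, current_sequence: str) -> BiasPotential:
    bias.update(current_sequence)
    return bias


@dataclass
class FlatnessReport:
    """Per-position type marginals and min/max population ratios."""

    marginals: pd.DataFrame  # columns: position, type, frequency
    ratios: dict  # position -> least/most populated type frequency ratio

    @property
    def min_ratio(self) -> float:
        return min(self.ratios.values()) if self.ratios else float("nan")


def flatness_report(pop, space: SequenceSpace) -> FlatnessReport:
    """Marginal frequency of each type at each mutable position, plus the
    ratio of least to most populated type (0 flags an unvisited type)."""
    if pop.total == 0:
        raise ValueError("empty population table")
    rows = []
    ratios = {}
    for k, (pos, ts) in enumerate(zip(space.positions, space.allowed_types)):
        counts = {t: 0 for t in ts}
        for seq, c in pop.counts.items():
            counts[seq[k]] += c
        freqs = {t: counts[t] / pop.total for t in ts}
        for t in ts:
            rows.append({"position": pos, "type": t, "frequency": freqs[t]})
        fmax = max(freqs.values())
        ratios[pos] = (min(freqs.values()) / fmax) if fmax > 0 else 0.0
    return FlatnessReport(pd.DataFrame(rows), ratios)


def run_flattening(
    matrix: EnergyMatrix,
    config,
    *,
    e0: float = 0.2,
    E0: float = 50.0,
    update_period: int = 1000,
    pair_terms: bool = False,
    adapt_steps: int | None = None,
    production_steps: int | None = None,
    average_tail: float = 0.5,
    stage_label: str = "stage1",
):
    """Flatten a state's sequence landscape, then record its biased
    populations under the frozen bias.

    Two phases.  *Adaptation*: a Metropolis chain on ``E + E_B`` with the
    bias penalized every ``update_period`` steps (Wang-Landau / well-
    tempered scheme).  The frozen bias returned is the time average of the
    adapting bias over the last ``average_tail`` fraction of the updates —
    averaging removes the O(sqrt(e0*kT)) jitter of the instantaneous bias
    without touching the adaptation dynamics.  *Production*: a fresh chain
    with the frozen bias records the biased population table used for
    free-energy extraction.

    Returns ``(bias, population_table)``.
    """
    from . import sampler as _sampler

    if not 0.0 <= average_tail <= 1.0:
        raise ValueError("average_tail must be in [0, 1]")
    adapt_steps = int(adapt_steps if adapt_steps is not None else config.n_steps)
    production_steps = int(
        production_steps if production_steps is not None else config.n_steps
    )
    bias = BiasPotential(
        matrix.space, e0=e0, E0=E0, update_period=update_period, pair_terms=pair_terms
    )
    _sampler._adapt_bias(
        matrix, bias, config, adapt_steps, average_tail=average_tail
    )
    prod_cfg = config.replace(n_steps=production_steps, seed=config.seed + 1)
    pop = _sampler.run_mc(matrix, bias, prod_cfg, stage_label=stage_label)
    return bias, pop
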