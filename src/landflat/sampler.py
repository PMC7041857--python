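"""Metropolis Monte Carlo over (sequence x rotamer) space, with optional
bias energy and Replica Exchange (parallel tempering).

Moves reassign the (type, rotamer) combo at one position (probability
``1 - move_mix``) or at two distinct positions (``move_mix``), drawing the
new combo uniformly from the position's allowed set, so proposals are
symmetric and the plain Metropolis ratio applies.  The chain runs on
``total_energy(state) + bias_energy(sequence)``; sequence visits are
recorded every ``record_interval`` steps into a :class:`PopulationTable`,
the raw material of all free-energy estimates.

REMC runs one chain per rung of a thermal-energy ladder (default: the
eight rungs 0.17 ... 3.0 kcal/mol), attempting adjacent-pair configuration
swaps every ``swap_interval`` steps with alternating parity.  All replicas
share the same bias.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .adaptive_bias import BiasPotential
from .energy_model import EnergyMatrix, Move, SequenceSpace, StateAssignment

__all__ = [
    "DEFAULT_LADDER",
    "SamplerConfig",
    "PopulationTable",
    "metropolis_accept",
    "remc_swap_accept",
    "propose_move",
    "random_state",
    "run_mc",
    "run_remc",
]

#: Thermal-energy ladder (kcal/mol) used for replica exchange; the
#: 0.59 kcal/mol rung corresponds to kT at ~296 K and is the default
#: rung that populations are read from.
DEFAULT_LADDER = (0.17, 0.26, 0.39, 0.59, 0.88, 1.33, 2.0, 3.0)

_CHUNK = 1 << 19  # MC steps per pre-drawn random block


@dataclass(frozen=True)
class SamplerConfig:
    """Run parameters for a single-temperature or REMC simulation."""

    kT: float = 0.59
    n_steps: int = 1_000_000
    seed: int = 0
    move_mix: float = 0.2
    record_interval: int = 10
    ladder: tuple = DEFAULT_LADDER
    swap_interval: int = 500

    def __post_init__(self):
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if not 0.0 <= self.move_mix <= 1.0:
            raise ValueError("move_mix must lie in [0, 1]")
        if min(self.n_steps, self.swap_interval, self.record_interval) < 1:
            raise ValueError("n_steps, swap_interval, record_interval must be >= 1")
        lad = tuple(float(k) for k in self.ladder)
        if any(k <= 0 for k in lad):
            raise ValueError("ladder thermal energies must be positive")
        if any(b <= a for a, b in zip(lad, lad[1:])):
            raise ValueError("ladder must be strictly increasing")
        object.__setattr__(self, "ladder", lad)

    def replace(self, **kw) -> "SamplerConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class PopulationTable:
    """Per-sequence visit counts from one simulation stage."""

    counts: dict
    total: int
    stage_label: str = ""
    kT_recorded: float = float("nan")
    bias_applied: bool = False
    meta: dict = field(default_factory=dict)
    block_counts: list | None = None

    def __post_init__(self):
        if self.total != sum(self.counts.values()):
            raise ValueError("total must equal the sum of counts")

    def frequencies(self) -> dict:
        return {s: c / self.total for s, c in self.counts.items()}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# stage\t{self.stage_label}\n")
            fh.write(f"# kT\t{self.kT_recorded}\n")
            fh.write(f"# bias_applied\t{int(self.bias_applied)}\n")
            for k, v in self.meta.items():
                fh.write(f"# {k}\t{v}\n")
            fh.write("sequence\tcount\tfrequency\n")
            for s in sorted(self.counts):
                fh.write(f"{s}\t{self.counts[s]}\t{self.counts[s] / self.total:.10g}\n")

    @classmethod
    def from_tsv(cls, path) -> "PopulationTable":
        meta, counts = {}, {}
        stage, kT, biased = "", float("nan"), False
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("\t")
                    if key == "stage":
                        stage = val
                    elif key == "kT":
                        kT = float(val)
                    elif key == "bias_applied":
                        biased = bool(int(val))
                    else:
                        meta[key] = val
                elif line.strip() and not line.startswith("sequence"):
                    s, c, _ = line.split("\t")
                    counts[s] = int(c)
        return cls(counts, sum(counts.values()), stage, kT, biased, meta)


# -- elementary operations (pure-Python reference surface) ------------------

def metropolis_accept(dE: float, kT: float, u: float) -> bool:
    """Accept iff ``u < min(1, exp(-dE/kT))``."""
    if kT <= 0:
        raise ValueError("kT must be positive")
    return dE <= 0.0 or u < math.exp(-dE / kT)


def remc_swap_accept(E_a: float, E_b: float, kT_a: float, kT_b: float, u: float) -> bool:
    """Parallel-tempering swap criterion for configurations at two rungs."""
    if kT_a == kT_b:
        raise ValueError("swap requires distinct thermal energies")
    arg = (1.0 / kT_a - 1.0 / kT_b) * (E_a - E_b)
    return arg >= 0.0 or u < math.exp(arg)


def random_state(space: SequenceSpace, rng: np.random.Generator) -> StateAssignment:
    """Uniform random (type, rotamer) draw at every position."""
    type_at, rot_at = {}, {}
    for pos in space.all_positions:
        ts = space.types_at(pos)
        t = ts[rng.integers(len(ts))]
        type_at[pos] = t
        rot_at[pos] = int(rng.integers(space.rotamers_at(pos, t)))
    return StateAssignment(type_at, rot_at)


def propose_move(
    state: StateAssignment,
    space: SequenceSpace,
    move_mix: float,
    rng: np.random.Generator,
) -> Move:
    """Symmetric 1- or 2-position move proposal.

    Positions are drawn uniformly among all mutable + flexible positions;
    the new (type, rotamer) is uniform over the position's allowed combos.
    Falls back to a 1-position move when fewer than 2 positions exist.
    """
    positions = space.all_positions
    two = rng.random() < move_mix and len(positions) >= 2
    chosen = rng.choice(len(positions), size=2 if two else 1, replace=False)
    move = []
    for k in chosen:
        pos = positions[int(k)]
        combos = [
            (t, r)
            for t in space.types_at(pos)
            for r in range(space.rotamers_at(pos, t))
        ]
        t, r = combos[int(rng.integers(len(combos)))]
        move.append((pos, t, r))
    return move


# -- dense compilation ------------------------------------------------------

@dataclass
class _Compiled:
    positions: tuple
    n_mut: int
    ncomb: np.ndarray
    comb_type: np.ndarray
    diag: np.ndarray
    pairm: np.ndarray
    strides: np.ndarray
    n_seq: int
    combos: list  # per position: list of (type, rotamer)
    space: SequenceSpace


def _compile(matrix: EnergyMatrix) -> _Compiled:
    space = matrix.space
    positions = space.all_positions
    n_pos = len(positions)
    n_mut = len(space.positions)
    combos = []
    for pos in positions:
        combos.append(
            [(t, r) for ti, t in enumerate(space.types_at(pos))
             for r in range(space.rotamers_at(pos, t))]
        )
    ncomb = np.array([len(c) for c in combos], dtype=np.int64)
    cmax = int(ncomb.max())
    comb_type = np.zeros((n_pos, cmax), dtype=np.int64)
    diag = np.zeros((n_pos, cmax))
    index_of = []
    for i, pos in enumerate(positions):
        lookup = {}
        ts = space.types_at(pos)
        for c, (t, r) in enumerate(combos[i]):
            comb_type[i, c] = ts.index(t)
            diag[i, c] = matrix.diag_energy(pos, t, r)
            lookup[(t, r)] = c
        index_of.append(lookup)
    pairm = np.zeros((n_pos, n_pos, cmax, cmax))
    pos_index = {p: i for i, p in enumerate(positions)}
    for ((pi, ti, ri), (pj, tj, rj)), e in matrix.pair.items():
        i, j = pos_index[pi], pos_index[pj]
        ci, cj = index_of[i][(ti, ri)], index_of[j][(tj, rj)]
        pairm[i, j, ci, cj] = e
        pairm[j, i, cj, ci] = e
    ntypes = [len(ts) for ts in space.allowed_types]
    strides = np.ones(n_mut, dtype=np.int64)
    for k in range(n_mut - 2, -1, -1):
        strides[k] = strides[k + 1] * ntypes[k + 1]
    n_seq = space.n_sequences
    if n_seq > 50_000_000:
        raise ValueError(f"sequence space too large to tabulate ({n_seq})")
    return _Compiled(positions, n_mut, ncomb, comb_type, diag, pairm,
                     strides, n_seq, combos, space)


def _bias_arrays(cm: _Compiled, bias: BiasPotential | None):
    tmax = max(int(cm.comb_type.max()) + 1, 1)
    if bias is None:
        return np.zeros((cm.n_mut, tmax)), np.zeros((1, 1, 1, 1)), False
    bspace = bias.space
    if (bspace.positions != cm.space.positions
            or bspace.allowed_types != cm.space.allowed_types):
        raise ValueError("bias and matrix are defined on different spaces")
    return bias._single, bias._pair, bias.pair_enabled


def _decode_counts(cm: _Compiled, counts: np.ndarray) -> dict:
    out = {}
    types = cm.space.allowed_types
    for idx in np.nonzero(counts)[0]:
        rem = int(idx)
        chars = []
        for k in range(cm.n_mut):
            q, rem = divmod(rem, int(cm.strides[k]))
            chars.append(types[k][q])
        out["".join(chars)] = int(counts[idx])
    return out


def _initial_arrays(cm: _Compiled, rng, initial: StateAssignment | None):
    comb = np.empty(len(cm.positions), dtype=np.int64)
    if initial is None:
        for i in range(len(cm.positions)):
            comb[i] = rng.integers(cm.ncomb[i])
    else:
        initial.validate(cm.space)
        for i, pos in enumerate(cm.positions):
            key = (initial.type_at[pos], initial.rotamer_at[pos])
            comb[i] = cm.combos[i].index(key)
    cur_type = np.array(
        [cm.comb_type[i, comb[i]] for i in range(cm.n_mut)], dtype=np.int64
    )
    return comb, cur_type


def _drive(cm, comb, cur_type, bs, bp, pair_on, kT, config, n_steps, rng, counts,
           step_offset=0, adapt=False, update_period=1000, e0=0.2, E0=50.0,
           tail_start=np.iinfo(np.int64).max, bsum=None, bpsum=None):
    """Run ``n_steps`` in chunks of pre-drawn randoms; returns the number
    of tail bias snapshots accumulated."""
    if bsum is None:
        bsum = np.zeros_like(bs)
    if bpsum is None:
        bpsum = np.zeros_like(bp)
    n_acc = 0
    done = 0
    while done < n_steps:
        n = min(_CHUNK, n_steps - done)
        rand = rng.random((n, 6))
        n_acc += _kernel.run_chain(
            comb, cur_type, cm.diag, cm.pairm, cm.comb_type, cm.ncomb, cm.n_mut,
            bs, bp, pair_on, kT, config.move_mix, rand,
            step_offset + done, config.record_interval, counts, cm.strides,
            adapt, update_period, e0, E0, tail_start, bsum, bpsum,
        )
        done += n
    return n_acc, bsum, bpsum


def run_mc(
    matrix: EnergyMatrix,
    bias: BiasPotential | None,
    config: SamplerConfig,
    *,
    stage_label: str = "",
    initial: StateAssignment | None = None,
    n_blocks: int = 1,
) -> PopulationTable:
    """Metropolis chain on ``E + E_B`` with a frozen bias.

    Sequence visits are recorded every ``config.record_interval`` steps.
    With ``n_blocks > 1`` the run is split into contiguous blocks and
    per-block counts are kept (for block-bootstrap error bars).
    Reproducible: the table is a pure function of (matrix, bias, config).
    """
    cm = _compile(matrix)
    bs, bp, pair_on = _bias_arrays(cm, bias)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    comb, cur_type = _initial_arrays(cm, rng, initial)
    counts_total = np.zeros(cm.n_seq, dtype=np.int64)
    block_dicts = []
    edges = np.linspace(0, config.n_steps, max(n_blocks, 1) + 1).astype(int)
    offset = 0
    for b in range(max(n_blocks, 1)):
        counts = np.zeros(cm.n_seq, dtype=np.int64)
        nb = int(edges[b + 1] - edges[b])
        _drive(cm, comb, cur_type, bs, bp, pair_on, config.kT, config, nb, rng,
               counts, step_offset=offset)
        offset += nb
        counts_total += counts
        if n_blocks > 1:
            block_dicts.append(_decode_counts(cm, counts))
    return PopulationTable(
        counts=_decode_counts(cm, counts_total),
        total=int(counts_total.sum()),
        stage_label=stage_label,
        kT_recorded=config.kT,
        bias_applied=bias is not None,
        meta={
            "seed": config.seed,
            "n_steps": config.n_steps,
            "bias_hash": bias.content_hash() if bias is not None else "-",
        },
        block_counts=block_dicts or None,
    )


def _adapt_bias(matrix, bias: BiasPotential, config: SamplerConfig,
                adapt_steps: int, average_tail: float = 0.5) -> None:
    """Adaptation phase of landscape flattening (mutates ``bias``).

    The bias is updated in place every ``bias.update_period`` steps; at the
    end, if ``average_tail > 0``, the bias arrays are replaced by their
    time average over the last ``average_tail`` fraction of the updates.
    """
    cm = _compile(matrix)
    bs, bp, pair_on = _bias_arrays(cm, bias)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    comb, cur_type = _initial_arrays(cm, rng, None)
    counts = np.zeros(cm.n_seq, dtype=np.int64)
    tail_start = (
        int(adapt_steps * (1.0 - average_tail)) + 1
        if average_tail > 0
        else np.iinfo(np.int64).max
    )
    n_acc, bsum, bpsum = _drive(
        cm, comb, cur_type, bs, bp, pair_on, config.kT, config, adapt_steps, rng,
        counts, adapt=True, update_period=bias.update_period,
        e0=bias.e0, E0=bias.E0, tail_start=tail_start,
    )
    if n_acc > 0:
        bias._single[:] = bsum / n_acc
        if pair_on:
            bias._pair[:] = bpsum / n_acc


def run_remc(
    matrix: EnergyMatrix,
    bias: BiasPotential | None,
    config: SamplerConfig,
    *,
    stage_label: str = "",
) -> list[PopulationTable]:
    """Replica-exchange MC: one chain per ladder rung, adjacent-pair
    configuration swaps every ``swap_interval`` steps (alternating even /
    odd pairs), all replicas sharing the same frozen bias.

    Returns one :class:`PopulationTable` per rung, recorded at that rung's
    thermal energy.  A single-rung ladder reduces exactly to :func:`run_mc`.
    """
    ladder = config.ladder
    if len(ladder) == 0:
        raise ValueError("ladder must declare at least one thermal energy")
    if len(ladder) == 1:
        pop = run_mc(matrix, bias, config.replace(kT=ladder[0]),
                     stage_label=stage_label)
        return [pop]
    cm = _compile(matrix)
    bs, bp, pair_on = _bias_arrays(cm, bias)
    n_rep = len(ladder)
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(n_rep + 1)
    rngs = [np.random.default_rng(s) for s in children[:n_rep]]
    swap_rng = np.random.default_rng(children[n_rep])
    states = [_initial_arrays(cm, rngs[r], None) for r in range(n_rep)]
    counts = [np.zeros(cm.n_seq, dtype=np.int64) for _ in range(n_rep)]
    offsets = [0] * n_rep

    def biased_energy(r):
        comb, cur_type = states[r]
        e = _kernel.total_energy_arrays(comb, cm.diag, cm.pairm)
        for k in range(cm.n_mut):
            e += bs[k, cur_type[k]]
        if pair_on:
            e += _kernel._pair_bias_total(cur_type, bp)
        return e

    remaining = config.n_steps
    segment = 0
    while remaining > 0:
        n = min(config.swap_interval, remaining)
        for r in range(n_rep):
            comb, cur_type = states[r]
            _drive(cm, comb, cur_type, bs, bp, pair_on, ladder[r], config, n,
                   rngs[r], counts[r], step_offset=offsets[r])
            offsets[r] += n
        remaining -= n
        if remaining > 0:
            for a in range(segment % 2, n_rep - 1, 2):
                u = swap_rng.random()
                if remc_swap_accept(
                    biased_energy(a), biased_energy(a + 1), ladder[a], ladder[a + 1], u
                ):
                    states[a], states[a + 1] = states[a + 1], states[a]
        segment += 1

    tables = []
    for r in range(n_rep):
        tables.append(
            PopulationTable(
                counts=_decode_counts(cm, counts[r]),
                total=int(counts[r].sum()),
                stage_label=stage_label,
                kT_recorded=ladder[r],
                bias_applied=bias is not None,
                meta={
                    "seed": config.seed,
                    "n_steps": config.n_steps,
                    "rung": r,
                    "bias_hash": bias.content_hash() if bias is not None else "-",
                },
            )
        )
    return tables


def pool_populations(tables: list) -> PopulationTable:
    """Pool counts across replicas (an option; the default protocol reads
    one rung).  The pooled table carries no single thermal energy."""
    counts: dict = {}
    for t in tables:
        for s, c in t.counts.items():
            counts[s] = counts.get(s, 0) + c
    return PopulationTable(
        counts=counts,
        total=sum(counts.values()),
        stage_label=tables[0].stage_label if tables else "",
        kT_recorded=float("nan"),
        bias_applied=any(t.bias_applied for t in tables),
    )
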