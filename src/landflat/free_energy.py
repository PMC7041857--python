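"""From visit populations to relative free energies and rankings.

The central identity: normalizing the sampled population of a sequence S
gives a biased free energy up to a state constant,

    G~_X(S) = -kT ln p~_X(S)   (+ const),      X = apo or holo,

and since both stages run under the *same* frozen bias, the bias cancels
from the double difference

    ddG(S) = -kT ln [p~_H(S)/p~_H(R)] + kT ln [p~_A(S)/p~_A(R)],

which is the binding free energy of S relative to the reference R with no
bias at all.  Specificity is a difference of two such ddG columns toward
two ligands; the catalytic efficiency combines relative activation and
binding free energies as kT log of k_cat/K_M relative to wild type.

Sequences visited fewer than ``visit_threshold`` times (default 1000) in
either stage are left unscored rather than estimated from noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .adaptive_bias import BiasPotential
from .sampler import PopulationTable

__all__ = [
    "populations_to_free_energies",
    "unbias_free_energy",
    "relative_binding_free_energy",
    "specificity",
    "catalytic_efficiency",
    "rank_variants",
    "top_report",
]

DEFAULT_VISIT_THRESHOLD = 1000
DEFAULT_FOLD_THRESHOLD = 5.0  # kcal/mol


def _resolve_kT(pop: PopulationTable, kT):
    if kT is None:
        if not np.isfinite(pop.kT_recorded):
            raise ValueError("population table carries no kT; pass kT explicitly")
        return pop.kT_recorded
    return float(kT)


def populations_to_free_energies(
    pop: PopulationTable, kT: float | None = None, visit_threshold: int = 0
) -> pd.Series:
    """Biased sequence free energies ``-kT ln(count/total)`` (kcal/mol).

    Reported up to a common additive constant (the -kT ln Z term is
    unknowable and cancels from all differences).  Sequences below the
    visit threshold are excluded.
    """
    if pop.total == 0:
        raise ValueError("empty population table")
    kT = _resolve_kT(pop, kT)
    items = {s: c for s, c in pop.counts.items() if c > max(visit_threshold, 0)}
    if not items:
        raise ValueError("no sequence passes the visit threshold")
    seqs = sorted(items)
    g = -kT * np.log(np.array([items[s] for s in seqs]) / pop.total)
    return pd.Series(g, index=seqs, name="G_tilde")


def unbias_free_energy(g_tilde: pd.Series, bias: BiasPotential) -> pd.Series:
    """Remove the bias: ``G(S) = G~(S) - E_B(S)`` (same additive constant)."""
    eb = np.array([bias.bias_energy(s) for s in g_tilde.index])
    out = g_tilde - eb
    out.name = "G"
    return out


def relative_binding_free_energy(
    pop_holo: PopulationTable,
    pop_apo: PopulationTable,
    reference: str,
    kT: float | None = None,
    visit_threshold: int = DEFAULT_VISIT_THRESHOLD,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Relative binding free energies from the two-stage populations.

    Both tables must come from runs under the same frozen bias at the same
    thermal energy; the bias never enters the formula (it cancels).  Rows
    are produced for every sequence above ``visit_threshold`` in *both*
    stages.  With ``n_bootstrap > 0`` and block-resolved tables, a block
    bootstrap standard error is attached per sequence.

    Returns a DataFrame indexed by sequence with columns ``ddG_bind``,
    ``visits_stage1`` (apo), ``visits_stage2`` (holo) and optionally
    ``ddG_err``.
    """
    if kT is None:
        kTh, kTa = pop_holo.kT_recorded, pop_apo.kT_recorded
        if np.isfinite(kTh) and np.isfinite(kTa) and not np.isclose(kTh, kTa):
            raise ValueError(
                f"stage thermal energies differ ({kTh} vs {kTa}); "
                "extract both stages at the same kT"
            )
        kT = _resolve_kT(pop_holo, None)
    if pop_holo.counts.get(reference, 0) < visit_threshold or (
        pop_apo.counts.get(reference, 0) < visit_threshold
    ):
        raise ValueError(
            f"reference sequence {reference!r} below the visit threshold"
        )

    def _ddg(holo_counts, apo_counts, seqs):
        ch_r, ca_r = holo_counts[reference], apo_counts[reference]
        out = {}
        for s in seqs:
            ch, ca = holo_counts.get(s, 0), apo_counts.get(s, 0)
            if ch > 0 and ca > 0 and ch_r > 0 and ca_r > 0:
                out[s] = -kT * np.log(ch / ch_r) + kT * np.log(ca / ca_r)
        return out

    scored = sorted(
        s
        for s in pop_holo.counts
        if pop_holo.counts[s] >= visit_threshold
        and pop_apo.counts.get(s, 0) >= visit_threshold
    )
    ddg = _ddg(pop_holo.counts, pop_apo.counts, scored)
    df = pd.DataFrame(
        {
            "ddG_bind": [ddg[s] for s in scored],
            "visits_stage1": [pop_apo.counts[s] for s in scored],
            "visits_stage2": [pop_holo.counts[s] for s in scored],
        },
        index=pd.Index(scored, name="sequence"),
    )
    if n_bootstrap > 0:
        if not (pop_holo.block_counts and pop_apo.block_counts):
            raise ValueError("bootstrap needs block-resolved population tables")
        rng = np.random.default_rng(seed)
        samples = {s: [] for s in scored}
        nh, na = len(pop_holo.block_counts), len(pop_apo.block_counts)
        for _ in range(n_bootstrap):
            hb = [pop_holo.block_counts[i] for i in rng.integers(nh, size=nh)]
            ab = [pop_apo.block_counts[i] for i in rng.integers(na, size=na)]
            hc: dict = {}
            ac: dict = {}
            for blk in hb:
                for s, c in blk.items():
                    hc[s] = hc.get(s, 0) + c
            for blk in ab:
                for s, c in blk.items():
                    ac[s] = ac.get(s, 0) + c
            if hc.get(reference, 0) == 0 or ac.get(reference, 0) == 0:
                continue
            boot = _ddg(hc, ac, scored)
            for s, v in boot.items():
                samples[s].append(v)
        df["ddG_err"] = [
            float(np.std(samples[s], ddof=1)) if len(samples[s]) > 1 else np.nan
            for s in scored
        ]
    return df


def specificity(ddG_target: pd.Series, ddG_competitor: pd.Series) -> pd.Series:
    """Binding free-energy difference between two ligands,
    ``ddG_spec = ddG_target - ddG_competitor`` per sequence.

    Sequences scored for only one ligand are left out (unscored).
    Equivalent, in one step, to flattening the competitor-bound complex
    and sampling the target-bound complex.
    """
    common = ddG_target.index.intersection(ddG_competitor.index)
    out = (ddG_target.loc[common] - ddG_competitor.loc[common]).astype(float)
    out.name = "ddG_spec"
    return out


def catalytic_efficiency(ddG_act: pd.Series, ddG_bind: pd.Series) -> pd.Series:
    """Relative catalytic efficiency, ``kT log[(kcat/KM) / (kcat/KM)_WT]``
    in kcal/mol: ``eff = -ddG_act - ddG_bind``.

    Transition-state theory signs: a lower activation free energy
    (ddG_act < 0, larger kcat) and tighter substrate binding
    (ddG_bind < 0, smaller KM) both increase the efficiency.
    """
    common = ddG_act.index.intersection(ddG_bind.index)
    out = (-ddG_act.loc[common] - ddG_bind.loc[common]).astype(float)
    out.name = "eff"
    return out


def rank_variants(
    table: pd.DataFrame,
    criterion: str = "ddG_bind",
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    fold_column: str = "fold",
) -> pd.DataFrame:
    """Stability-filter and rank a free-energy table.

    Sequences whose relative folding free energy is >= ``fold_threshold``
    kcal/mol are excluded from the ranking (flagged with a reason); the
    rest are sorted ascending by ``criterion`` with ties broken by
    lexicographic sequence order.  Adds ``rank`` (nullable integer),
    ``filtered`` and ``filter_reason`` columns.
    """
    if criterion not in table.columns:
        raise KeyError(f"unknown ranking criterion {criterion!r}")
    out = table.copy()
    if fold_column in out.columns:
        filtered = out[fold_column].astype(float) >= fold_threshold
    else:
        filtered = pd.Series(False, index=out.index)
    out["filtered"] = filtered
    out["filter_reason"] = np.where(
        filtered, f"fold >= {fold_threshold:g} kcal/mol", ""
    )
    # deterministic tie-break: ascending criterion, then sequence order
    keep = out.loc[~filtered]
    order = sorted(keep.index, key=lambda s: (keep.at[s, criterion], s))
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order)
    out["rank"] = ranks.reindex(out.index).astype("Int64")
    return pd.concat([out.loc[order], out.loc[filtered]])


def top_report(ranked: pd.DataFrame, n: int = 20, criterion: str = "ddG_bind") -> str:
    """Plain-text top-N report: rank, variant, folding, criterion value."""
    rows = ranked.loc[~ranked["filtered"]].nsmallest(n, criterion)
    has_fold = "fold" in ranked.columns and ranked["fold"].notna().any()
    fold_head = f" {'fold':>8} " if has_fold else ""
    lines = [f"{'rank':>4}  {'variant':<10}{fold_head} {criterion:>10}"]
    for seq, row in rows.iterrows():
        fold = f" {row['fold']:>8.2f} " if has_fold else ""
        lines.append(
            f"{int(row['rank']):>4}  {seq:<10}{fold} {row[criterion]:>10.3f}"
        )
    return "\n".join(lines)
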