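"""Ensemble characterization: per-reaction summaries and KS-relevant fluxes.

Ensembles (groups of simulation records) are summarized by per-reaction
medians and standard deviations of kinetic constants or steady-state fluxes,
grouped either by the simulated condition ("sC") or by filter satisfaction
("fC").  A reaction is a relevant flux when the two-sample Kolmogorov-Smirnov
test separates its flux distributions for every pair of conditions at the
chosen significance level (default 0.05, no multiple-testing correction by
default; Benjamini-Hochberg available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnsembleSummary",
    "RelevantFluxReport",
    "summarize",
    "ks_relevant_fluxes",
    "GROUP_BY_CONDITION",
    "GROUP_BY_FILTER",
]

GROUP_BY_CONDITION = "by_condition"  # sC grouping
GROUP_BY_FILTER = "by_filter"        # fC grouping


@dataclass
class EnsembleSummary:
    phenotype_id: str
    grouping_mode: str
    n_members: int
    median: pd.Series | None
    std: pd.Series | None

    @property
    def empty(self) -> bool:
        return self.n_members == 0


def summarize(
    values: pd.DataFrame,
    membership: pd.DataFrame,
    grouping_mode: str = GROUP_BY_FILTER,
    phenotypes: Sequence[str] | None = None,
) -> dict[str, EnsembleSummary]:
    """Per-phenotype medians and standard deviations of ``values``.

    ``values`` holds one row per simulation record (aligned with
    ``membership``) and one column per reaction — either kinetic constants or
    steady-state fluxes.  With ``by_condition`` a record belongs to the group
    of its simulated condition; with ``by_filter`` to every phenotype whose
    filter it satisfies, regardless of condition.  Empty ensembles are
    flagged, never raised.
    """
    if len(values) != len(membership):
        raise ValueError("values and membership must have one row per record")
    phen_cols = [c for c in membership.columns
                 if c not in ("parametrization_id", "condition_id")]
    if phenotypes is None:
        phenotypes = phen_cols
    out: dict[str, EnsembleSummary] = {}
    for e in phenotypes:
        if grouping_mode == GROUP_BY_CONDITION:
            mask = (membership["condition_id"] == e).to_numpy()
        elif grouping_mode == GROUP_BY_FILTER:
            mask = membership[e].to_numpy(dtype=bool)
        else:
            raise ValueError(f"unknown grouping mode {grouping_mode!r}")
        sub = values.iloc[mask]
        if len(sub) == 0:
            out[e] = EnsembleSummary(e, grouping_mode, 0, None, None)
        else:
            out[e] = EnsembleSummary(
                e, grouping_mode, len(sub),
                median=sub.median(axis=0), std=sub.std(axis=0, ddof=0),
            )
    return out


def summary_matrix(summaries: Mapping[str, EnsembleSummary]) -> pd.DataFrame:
    """Heatmap-ready matrix: reactions (rows) x groups (columns) of medians."""
    cols = {e: s.median for e, s in summaries.items() if not s.empty}
    return pd.DataFrame(cols)


@dataclass
class RelevantFluxReport:
    alpha: float
    pairwise_p: pd.DataFrame        # reactions x condition pairs
    relevant: set[str]
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)
    corrected: bool = False


def _ks_p(a: np.ndarray, b: np.ndarray) -> float:
    # exact null distribution for small samples, asymptotic otherwise
    method = "exact" if max(len(a), len(b)) <= 50 else "asymp"
    return float(stats.ks_2samp(a, b, method=method).pvalue)


def ks_relevant_fluxes(
    samples: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
    correction: str | None = None,
) -> RelevantFluxReport:
    """Identify fluxes whose distributions differ for every pair of conditions.

    ``samples`` maps condition id -> DataFrame (records x reactions).  For
    each reaction and each unordered pair of conditions a two-sample KS test
    is run; a reaction is relevant iff p < alpha for all pairs.  Pairs where a
    condition has fewer than two samples are skipped and reported — a reaction
    with a skipped pair cannot be relevant.  ``correction="bh"`` applies
    Benjamini-Hochberg across all tests before the relevance call.
    """
    conditions = list(samples)
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    reactions = list(samples[conditions[0]].columns)
    for cid in conditions[1:]:
        if list(samples[cid].columns) != reactions:
            raise ValueError("all conditions must cover the same reactions")

    pairs = list(combinations(conditions, 2))
    pair_labels = [f"{a}|{b}" for a, b in pairs]
    pmat = pd.DataFrame(np.nan, index=reactions, columns=pair_labels)
    skipped = []
    for (a, b), label in zip(pairs, pair_labels):
        if len(samples[a]) < 2 or len(samples[b]) < 2:
            skipped.append((a, b))
            continue
        for rid in reactions:
            pmat.loc[rid, label] = _ks_p(
                samples[a][rid].to_numpy(), samples[b][rid].to_numpy()
            )

    test_p = pmat.copy()
    corrected = False
    if correction == "bh":
        flat = test_p.to_numpy().ravel()
        ok = ~np.isnan(flat)
        flat[ok] = _benjamini_hochberg(flat[ok])
        test_p = pd.DataFrame(flat.reshape(pmat.shape),
                              index=pmat.index, columns=pmat.columns)
        corrected = True
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")

    if skipped:
        relevant: set[str] = set()
    else:
        relevant = set(test_p.index[(test_p < alpha).all(axis=1)])
    return RelevantFluxReport(alpha=alpha, pairwise_p=pmat, relevant=relevant,
                              skipped_pairs=skipped, corrected=corrected)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out
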