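"""Random-null comparison of mosaic statistics and regional ANOVA.

Whether a cone distribution carries more order than expected from soma
size alone is tested against an ensemble of random fields matched to the
observed field in class counts and window, generated by soma-constrained
random sequential placement. Observed scalar statistics (regularity
indices, effective radius, ...) are compared to the null replicate
distribution by z-score; an empirical rank test is available as an
alternative for users wary of the normal assumption at small replicate
counts.

Regional density comparisons use one-way ANOVA with Tukey HSD post-hoc
grouping, summarized as compact letters (regions sharing a letter are
statistically indistinct).
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import networkx as nx
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datatypes import ConeField, SomaSizes
from .drp import DensityRecoveryProfile, autocorrelogram, density_recovery_profile
from .errors import DegenerateFieldError
from .spatial import MosaicStats, SummaryStats, mosaic_summary
from .synth import gen_mixed_triple_field

__all__ = [
    "RandomNullEnsemble",
    "NullComparison",
    "RegionComparison",
    "simulate_null_ensemble",
    "compare_to_null",
    "compare_regions",
]


@dataclass
class RandomNullEnsemble:
    """Replicate statistics of soma-constrained random fields matched to an
    observed field (class counts and window)."""

    cone_class: str
    constraint: SomaSizes
    n_replicates: int
    replicate_stats: list[MosaicStats]
    #: per-replicate DRP (None where the replicate had no guarded references)
    replicate_drps: list[DensityRecoveryProfile | None] | None
    null_summary: dict[str, tuple[float, float]] = dc_field(default_factory=dict)

    def values_of(self, statistic: str) -> np.ndarray:
        vals = []
        for i in range(self.n_replicates):
            d = self.replicate_stats[i].scalars()
            if self.replicate_drps is not None:
                drp = self.replicate_drps[i]
                d["effective_radius"] = (drp.effective_radius if drp is not None
                                         else float("nan"))
            vals.append(d[statistic])
        return np.asarray(vals, dtype=float)


@dataclass
class NullComparison:
    statistic: str
    observed: float
    null_mean: float
    null_sd: float
    z_score: float
    p_value: float
    significant: bool
    alpha: float
    method: str = "z"


@dataclass
class RegionComparison:
    """One-way ANOVA across regions with Tukey HSD compact letters."""

    f_statistic: float
    p_value: float
    tukey: pd.DataFrame
    letters: dict[str, str]
    alpha: float


def _summarize(ensemble: RandomNullEnsemble) -> None:
    names = ["nnd_mean", "nnd_ri", "vd_mean", "vd_ri"]
    if ensemble.replicate_drps is not None:
        names.append("effective_radius")
    summary = {}
    for name in names:
        v = ensemble.values_of(name)
        finite = v[np.isfinite(v)]
        if finite.size >= 2:
            summary[name] = (float(np.mean(finite)), float(np.std(finite, ddof=1)))
        else:
            summary[name] = (float("nan"), float("nan"))
    ensemble.null_summary = summary


def simulate_null_ensemble(field: ConeField, cone_class: str,
                           soma: SomaSizes = SomaSizes(),
                           n_replicates: int = 20, seed: int = 0,
                           bin_width: float = 1.0, max_radius: float = 15.0,
                           compute_drp: bool = True,
                           max_attempts: int = 10_000) -> RandomNullEnsemble:
    """Generate matched random fields and collect their statistics.

    Each replicate is an independent soma-constrained random field with
    exactly the observed class counts in the observed window; per-replicate
    NND/Voronoi summaries (and optionally the DRP with its effective
    radius) are computed for ``cone_class``. Replicate seeds are derived
    deterministically from ``seed``.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 null replicates for a mean and SD")
    counts = field.class_counts()
    if counts.get(cone_class, 0) < 4:
        raise ValueError(f"class {cone_class!r} too sparse in the observed field")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    stats_list: list[MosaicStats] = []
    drps: list[DensityRecoveryProfile] | None = [] if compute_drp else None
    nan_summary = SummaryStats(*(float("nan"),) * 5)
    for s in child_seeds:
        rep = gen_mixed_triple_field(counts, soma=soma, window=field.window,
                                     seed=int(s), max_attempts=max_attempts)
        try:
            stats_list.append(mosaic_summary(rep, cone_class))
        except DegenerateFieldError:
            # too few interior cells in this replicate: contributes NaNs,
            # which the summary ignores
            stats_list.append(MosaicStats(cone_class, counts[cone_class], 0,
                                          nan_summary, nan_summary,
                                          np.asarray([]), np.asarray([])))
        if compute_drp:
            try:
                cg = autocorrelogram(rep, cone_class, max_radius)
                drps.append(density_recovery_profile(cg, bin_width))
            except ValueError:
                # e.g. no guarded reference cells in this replicate
                drps.append(None)
    ens = RandomNullEnsemble(cone_class=cone_class, constraint=soma,
                             n_replicates=n_replicates,
                             replicate_stats=stats_list, replicate_drps=drps)
    _summarize(ens)
    return ens


def compare_to_null(observed: float, ensemble: RandomNullEnsemble,
                    statistic: str, alpha: float = 0.05,
                    method: str = "z") -> NullComparison:
    """Compare an observed scalar statistic to the null ensemble.

    ``method="z"`` (default) computes a z-score against the replicate mean
    and SD and declares significance when |z| exceeds the two-sided normal
    critical value at ``alpha``. ``method="rank"`` uses the empirical
    two-sided rank of the observation among the replicates.
    """
    if statistic not in ensemble.null_summary:
        raise KeyError(f"statistic {statistic!r} not in ensemble summary")
    null_mean, null_sd = ensemble.null_summary[statistic]
    if method == "rank":
        vals = ensemble.values_of(statistic)
        vals = vals[np.isfinite(vals)]
        n = vals.size
        r = int(np.sum(vals <= observed))
        p = 2.0 * min(r + 1, n - r + 1) / (n + 1)
        p = min(1.0, p)
        z = (observed - null_mean) / null_sd if null_sd > 0 else (
            0.0 if observed == null_mean else float("inf"))
        return NullComparison(statistic, float(observed), null_mean, null_sd,
                              z, p, p < alpha, alpha, method="rank")
    if method != "z":
        raise ValueError("method must be 'z' or 'rank'")
    if null_sd == 0:
        if observed == null_mean:
            return NullComparison(statistic, float(observed), null_mean, 0.0,
                                  0.0, 1.0, False, alpha)
        # degenerate null: any deviation counts as significant
        zinf = float("inf") if observed > null_mean else float("-inf")
        return NullComparison(statistic, float(observed), null_mean, 0.0,
                              zinf, 0.0, True, alpha)
    z = (float(observed) - null_mean) / null_sd
    crit = float(sps.norm.ppf(1.0 - alpha / 2.0))
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return NullComparison(statistic, float(observed), null_mean, null_sd,
                          float(z), p, bool(abs(z) > crit), alpha)


def _compact_letters(names: Sequence[str], distinct: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: maximal cliques of the 'indistinct' graph
    each receive one letter; a region collects the letters of every clique
    it belongs to."""
    g = nx.Graph()
    g.add_nodes_from(names)
    for a in names:
        for b in names:
            if a < b and (a, b) not in distinct and (b, a) not in distinct:
                g.add_edge(a, b)
    cliques = sorted(nx.find_cliques(g), key=lambda c: (-len(c), sorted(c)))
    letters: dict[str, list[str]] = {n: [] for n in names}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, clique in enumerate(cliques):
        for n in clique:
            letters[n].append(alphabet[i % len(alphabet)])
    return {n: "".join(sorted(v)) for n, v in letters.items()}


def compare_regions(groups: Mapping[str, Sequence[float]],
                    alpha: float = 0.05) -> RegionComparison:
    """One-way ANOVA with Tukey HSD grouping across retinal regions.

    ``groups`` maps region name to a collection of per-field values (e.g.
    cone densities). Regions sharing a compact letter are statistically
    indistinct at ``alpha``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 regions to compare")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"region {k!r} has fewer than 2 values")
    f_stat, p_val = sps.f_oneway(*arrays.values())
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * v.size for k, v in arrays.items()])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    table = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    distinct = {
        (str(row["group1"]), str(row["group2"]))
        for _, row in table.iterrows() if bool(row["reject"])
    }
    letters = _compact_letters(sorted(arrays), distinct)
    return RegionComparison(float(f_stat), float(p_val), table, letters, alpha)
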