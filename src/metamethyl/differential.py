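"""Differential methylation between two sample groups (ice horizons).

Two complementary views:

* per contig x motif, a two-sample Kolmogorov-Smirnov test comparing the
  distribution of per-instance group means (or of per-instance standard
  errors across replicates) between the groups, with Benjamini-Hochberg
  correction across contigs;
* per motif instance, a pooled two-proportion test on modified/valid read
  counts, BH-corrected across instances, with the sign convention that a
  positive delta means more methylated in the second ("bottom") group.

Promoter-only variants restrict instances to windows upstream of annotated
start codons (default 60 bp).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneRecord
from .methylome_profile import InstanceProfile
from .motif_model import MotifInstance

DEFAULT_ALPHA = 0.01
EXACT_KS_LIMIT = 10_000


def ks_compare(xs, ys) -> tuple[float, float]:
    """Two-sample two-sided KS test: (d, p).

    d is the supremum distance between the two empirical CDFs.  The exact
    p-value is used when n*m <= 10000, the asymptotic one otherwise.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError("each sample needs at least 2 values for the KS test")
    method = "exact" if len(xs) * len(ys) <= EXACT_KS_LIMIT else "asymp"
    res = stats.ks_2samp(xs, ys, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    pvals = np.asarray(pvals, dtype=float)
    if len(pvals) == 0:
        return pvals
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def two_proportion_test(a_mod: int, a_cov: int,
                        b_mod: int, b_cov: int) -> float:
    """Two-sided p for equal modified fractions from pooled counts.

    Chi-squared on the 2x2 table without continuity correction; Fisher's
    exact test when any expected cell count is below 5.
    """
    table = np.array([[a_mod, a_cov - a_mod], [b_mod, b_cov - b_mod]],
                     dtype=float)
    n = table.sum()
    if n == 0:
        return 1.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected < 5).any() or (expected == 0).any():
        return float(stats.fisher_exact(table.astype(int))[1])
    stat = stats.chi2_contingency(table, correction=False)[0]
    return float(stats.chi2.sf(stat, 1))


def promoter_windows(genes: list[GeneRecord],
                     window: int = 60) -> dict[str, list[tuple[int, int]]]:
    """Per-contig promoter intervals (0-based half-open) upstream of genes."""
    wins: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        if g.strand == "+":
            iv = (g.start - window, g.start)
        else:
            iv = (g.end, g.end + window)
        wins.setdefault(g.contig, []).append(iv)
    return wins


def promoter_subset(instances: list[MotifInstance],
                    genes: list[GeneRecord],
                    window: int = 60) -> list[MotifInstance]:
    """Instances whose methylated base lies in a promoter window.

    The promoter is the ``window`` nucleotides upstream of the start codon:
    [start - window, start) for plus-strand genes, [end, end + window) for
    minus-strand genes.
    """
    wins = promoter_windows(genes, window)
    out = []
    for inst in instances:
        for lo, hi in wins.get(inst.contig, ()):
            if lo <= inst.site_pos < hi:
                out.append(inst)
                break
    return out


@dataclass
class ContigDiffResult:
    contig: str
    motif: str
    scope: str
    statistic_kind: str
    d: float
    p_raw: float
    p_adj: float
    n_a: int
    n_b: int
    status: str = "ok"


def contig_differential(profiles: list[InstanceProfile],
                        group_a: str = "top",
                        group_b: str = "bottom",
                        scope: str = "all_sites",
                        statistic_kind: str = "mean_fraction",
                        min_instances: int = 10,
                        alpha: float = DEFAULT_ALPHA,
                        genes: list[GeneRecord] | None = None,
                        promoter_window: int = 60) -> pd.DataFrame:
    """KS comparison of per-instance statistics per contig x motif.

    ``statistic_kind`` selects the per-instance value compared between
    groups: the coverage-weighted group mean fraction, or the standard
    error of the fraction across the group's replicate samples (a
    population-heterogeneity signal).  Contigs with fewer than
    ``min_instances`` instances having data in both groups are reported
    with status ``insufficient_data``.  BH correction runs across all
    tested contig x motif pairs; significance is flagged both at ``alpha``
    and at the conventional 0.05.
    """
    if scope == "promoter_only":
        if genes is None:
            raise ValueError("promoter_only scope requires gene annotations")
        keep = set()
        for inst in promoter_subset([p.instance for p in profiles], genes,
                                    promoter_window):
            keep.add((inst.contig, inst.strand, inst.site_pos))
        profiles = [p for p in profiles
                    if (p.instance.contig, p.instance.strand,
                        p.instance.site_pos) in keep]
    elif scope != "all_sites":
        raise ValueError(f"unknown scope {scope!r}")

    grouped: dict[tuple[str, str], list[InstanceProfile]] = {}
    for p in profiles:
        grouped.setdefault((p.instance.contig, p.instance.motif.bracketed),
                           []).append(p)

    results: list[ContigDiffResult] = []
    for (contig, motif), profs in sorted(grouped.items()):
        if statistic_kind == "mean_fraction":
            pairs = [(p.group_mean[group_a], p.group_mean[group_b])
                     for p in profs
                     if p.has_data(group_a) and p.has_data(group_b)]
        elif statistic_kind == "standard_error":
            pairs = [(p.group_se[group_a], p.group_se[group_b])
                     for p in profs
                     if not math.isnan(p.group_se.get(group_a, float("nan")))
                     and not math.isnan(p.group_se.get(group_b, float("nan")))]
        else:
            raise ValueError(f"unknown statistic_kind {statistic_kind!r}")
        if len(pairs) < min_instances:
            results.append(ContigDiffResult(
                contig, motif, scope, statistic_kind,
                float("nan"), float("nan"), float("nan"),
                len(pairs), len(pairs), status="insufficient_data"))
            continue
        xs = [a for a, _ in pairs]
        ys = [b for _, b in pairs]
        d, p = ks_compare(xs, ys)
        results.append(ContigDiffResult(contig, motif, scope, statistic_kind,
                                        d, p, float("nan"),
                                        len(xs), len(ys)))

    tested = [r for r in results if r.status == "ok"]
    if tested:
        adj = bh_adjust([r.p_raw for r in tested])
        for r, a in zip(tested, adj):
            r.p_adj = float(a)
    rows = [{
        "contig": r.contig, "motif": r.motif, "scope": r.scope,
        "statistic_kind": r.statistic_kind, "d": r.d,
        "p_raw": r.p_raw, "p_adj": r.p_adj,
        "n_a": r.n_a, "n_b": r.n_b, "status": r.status,
        "significant": bool(r.status == "ok" and r.p_adj <= alpha),
        "significant_05": bool(r.status == "ok" and r.p_adj <= 0.05),
    } for r in results]
    return pd.DataFrame(rows, columns=[
        "contig", "motif", "scope", "statistic_kind", "d", "p_raw", "p_adj",
        "n_a", "n_b", "status", "significant", "significant_05"])


def _nearest_gene(inst: MotifInstance,
                  genes: list[GeneRecord]) -> tuple[str | None, bool]:
    best_id, best_dist = None, None
    for g in genes:
        if g.contig != inst.contig:
            continue
        if g.start <= inst.site_pos < g.end:
            dist = 0
        else:
            dist = min(abs(inst.site_pos - g.start),
                       abs(inst.site_pos - (g.end - 1)))
        if best_dist is None or dist < best_dist:
            best_id, best_dist = g.gene_id, dist
    return best_id, best_dist


def instance_differential(profiles: list[InstanceProfile],
                          group_a: str = "top",
                          group_b: str = "bottom",
                          alpha: float = DEFAULT_ALPHA,
                          genes: list[GeneRecord] | None = None,
                          promoter_window: int = 60) -> pd.DataFrame:
    """Per-instance differential methylation between two groups.

    Read counts are pooled within each group; the test is a two-proportion
    chi-squared (Fisher exact at small expected counts).  delta =
    fraction(group_b) - fraction(group_a): with the default labels, positive
    values are more methylated in the bottom ice.  BH correction runs
    across all testable instances.
    """
    promoter_keep: set[tuple[str, str, int]] = set()
    if genes:
        for inst in promoter_subset([p.instance for p in profiles], genes,
                                    promoter_window):
            promoter_keep.add((inst.contig, inst.strand, inst.site_pos))

    rows = []
    for p in profiles:
        cov_a, mod_a = p.group_counts.get(group_a, (0, 0))
        cov_b, mod_b = p.group_counts.get(group_b, (0, 0))
        if cov_a == 0 or cov_b == 0:
            continue
        delta = mod_b / cov_b - mod_a / cov_a
        p_raw = two_proportion_test(mod_a, cov_a, mod_b, cov_b)
        gene_id, gene_dist = (None, None)
        if genes:
            gene_id, gene_dist = _nearest_gene(p.instance, genes)
        rows.append({
            "contig": p.instance.contig,
            "motif": p.instance.motif.bracketed,
            "strand": p.instance.strand,
            "site_pos": p.instance.site_pos,
            f"fraction_{group_a}": mod_a / cov_a,
            f"fraction_{group_b}": mod_b / cov_b,
            "delta": delta,
            "p_raw": p_raw,
            "flanking_gene": gene_id,
            "gene_distance": gene_dist,
            "in_promoter": (p.instance.contig, p.instance.strand,
                            p.instance.site_pos) in promoter_keep,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
        df["significant"] = df["p_adj"] <= alpha
        df["significant_05"] = df["p_adj"] <= 0.05
    else:
        df = pd.DataFrame(columns=[
            "contig", "motif", "strand", "site_pos",
            f"fraction_{group_a}", f"fraction_{group_b}", "delta", "p_raw",
            "flanking_gene", "gene_distance", "in_promoter", "p_adj",
            "significant", "significant_05"])
    return df
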