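"""Restriction-modification gene accounting and orphan-MTase statistics.

A methyltransferase (MTase) without a cognate restriction enzyme (REase) is
an *orphan*: its methylation cannot be serving classical immune defence and
is instead a signature of regulatory roles.  A strong community-wide surplus
of MTases over REases within a system type therefore indicates widespread
regulatory methylation.  The surplus statistic assumes, as a null, that each
role-assignable RM gene is independently an MTase or REase with probability
one half: z = (n_MTase - n_REase) / sqrt(N).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import RMGene, RM_SYSTEM_TYPES
from .motif_model import motifs_match


def count_by_type(rm_genes: list[RMGene]) -> pd.DataFrame:
    """Gene counts per system type: (n_mtase, n_rease, n_other).

    A ``combined`` restriction-and-modification gene (Type I/III fusions)
    increments both counters; specificity (S) subunits count as other.
    """
    counts = {t: {"n_mtase": 0, "n_rease": 0, "n_other": 0}
              for t in RM_SYSTEM_TYPES}
    for g in rm_genes:
        row = counts[g.system_type]
        if g.role == "MTase":
            row["n_mtase"] += 1
        elif g.role == "REase":
            row["n_rease"] += 1
        elif g.role == "combined":
            row["n_mtase"] += 1
            row["n_rease"] += 1
        else:
            row["n_other"] += 1
    df = pd.DataFrame(
        [{"system_type": t, **counts[t]} for t in RM_SYSTEM_TYPES])
    return df


def _gene_distance(a: RMGene, b: RMGene) -> float:
    """Gap in bp between two genes' intervals on the same contig."""
    if a.contig != b.contig:
        return float("inf")
    if None in (a.start, a.end, b.start, b.end):
        return float("inf")
    if a.end <= b.start:
        return b.start - a.end
    if b.end <= a.start:
        return a.start - b.end
    return 0.0


def orphan_mtases(rm_genes: list[RMGene],
                  genome_grouping: dict[str, str] | None = None,
                  linkage_kb: float = 5.0) -> list[tuple[RMGene, str]]:
    """MTases lacking a cognate REase, with the reason for orphan status.

    Within its genome group (MAG/bin id when known, else the contig), an
    MTase is *not* orphan iff some REase (or combined R-M gene) of the same
    system type either (a) recognises an IUPAC-compatible motif in either
    orientation, or (b), when either party's motif is unknown, lies within
    ``linkage_kb`` of it on the same contig (operon-style linkage).
    """
    def group_of(g: RMGene) -> str:
        if g.genome:
            return g.genome
        if genome_grouping:
            return genome_grouping.get(g.contig, g.contig)
        return g.contig

    by_group: dict[str, list[RMGene]] = {}
    for g in rm_genes:
        by_group.setdefault(group_of(g), []).append(g)

    orphans: list[tuple[RMGene, str]] = []
    for group, genes in by_group.items():
        reases = [g for g in genes if g.role in ("REase", "combined")]
        for mt in genes:
            if mt.role != "MTase":
                continue
            cognate = False
            saw_known_motif = False
            for re_ in reases:
                if re_.system_type != mt.system_type:
                    continue
                if mt.recognition_motif and re_.recognition_motif:
                    saw_known_motif = True
                    if motifs_match(mt.recognition_motif,
                                    re_.recognition_motif):
                        cognate = True
                        break
                else:
                    if _gene_distance(mt, re_) <= linkage_kb * 1000:
                        cognate = True
                        break
            if not cognate:
                reason = ("no_cognate_motif" if saw_known_motif
                          else "no_linked_rease")
                orphans.append((mt, reason))
    return orphans


def surplus_z(n_mtase: int, n_rease: int) -> tuple[float, float]:
    """Surplus of MTases over REases under a symmetric-binomial null.

    Null: each of N = n_mtase + n_rease genes is independently MTase or
    REase with probability 1/2, so n_mtase - n_rease has mean 0 and
    variance N; z = (n_mtase - n_rease)/sqrt(N), two-sided normal p.
    """
    n = n_mtase + n_rease
    if n == 0:
        raise ValueError("surplus_z needs at least one role-assignable gene")
    z = (n_mtase - n_rease) / np.sqrt(n)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return float(z), p


def surplus_z_permutation(n_mtase: int, n_rease: int, n_perm: int = 10_000,
                          rng: np.random.Generator | None = None
                          ) -> tuple[float, float]:
    """Permutation alternative: shuffle role labels, empirical two-sided p."""
    if rng is None:
        rng = np.random.default_rng(0)
    n = n_mtase + n_rease
    if n == 0:
        raise ValueError("needs at least one role-assignable gene")
    obs = abs(n_mtase - n_rease)
    draws = rng.binomial(n, 0.5, size=n_perm)
    null = np.abs(2 * draws - n)
    p = (1 + np.sum(null >= obs)) / (n_perm + 1)
    z = (n_mtase - n_rease) / np.sqrt(n)
    return float(z), float(p)


def surplus_report(rm_genes: list[RMGene],
                   count_combined_once: bool = False) -> pd.DataFrame:
    """Per-type surplus z and p; optionally count fused R-M genes once.

    With ``count_combined_once`` a combined gene contributes to neither
    side (its own MTase and REase activities cancel), a sensitivity check
    on the fusion-counting convention.
    """
    counts = count_by_type(rm_genes)
    if count_combined_once:
        n_combined = {t: sum(1 for g in rm_genes
                             if g.system_type == t and g.role == "combined")
                      for t in RM_SYSTEM_TYPES}
        counts["n_mtase"] = [m - n_combined[t] for m, t in
                             zip(counts["n_mtase"], counts["system_type"])]
        counts["n_rease"] = [r - n_combined[t] for r, t in
                             zip(counts["n_rease"], counts["system_type"])]
    zs, ps = [], []
    for _, row in counts.iterrows():
        n = row["n_mtase"] + row["n_rease"]
        if n == 0:
            zs.append(float("nan"))
            ps.append(float("nan"))
        else:
            z, p = surplus_z(int(row["n_mtase"]), int(row["n_rease"]))
            zs.append(z)
            ps.append(p)
    counts["z"] = zs
    counts["p"] = ps
    return counts
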