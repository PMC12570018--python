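"""Motif density in labelled regions and phage-host motif-profile matching.

A prophage depleted in a motif targeted by host restriction enzymes, or
enriched in a motif serving host regulation, leaves a density footprint:
we compare per-bp occurrence densities between a prophage and the host
remainder of its contig.  Separately, the set of motifs methylated on a
phage genome acts as a memory of the hosts whose methyltransferases wrote
them; matching that profile against candidate hosts' recognition sets
ranks plausible infection histories.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Region
from .motif_model import (IUPAC_SETS, Motif, count_occurrences,
                          information_bits, motifs_match,
                          reverse_complement)

logger = logging.getLogger(__name__)


@dataclass
class DensityResult:
    """Occurrence density of one motif in one region.

    ``spacing_bp`` is the display value length // count (truncated toward
    zero, the convention used for printed "one site every N bp" figures);
    ``spacing_exact`` keeps the real quotient.
    """

    motif: str
    region_label: str
    count: int
    length_bp: int
    density_per_bp: float
    spacing_bp: int | None
    spacing_exact: float


def motif_density(count: int, length_bp: int, motif: str = "",
                  region_label: str = "") -> DensityResult:
    """Density and spacing of ``count`` occurrences over ``length_bp``."""
    if length_bp <= 0:
        raise ValueError("region length must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    density = count / length_bp
    if count == 0:
        spacing_int, spacing_exact = None, float("nan")
    else:
        spacing_int = length_bp // count
        spacing_exact = length_bp / count
    return DensityResult(motif, region_label, count, length_bp,
                         density, spacing_int, spacing_exact)


def density_compare(count1: int, length1: int,
                    count2: int, length2: int) -> tuple[float, float]:
    """(density ratio region1/region2, two-sided p) for equal densities.

    Positions are treated as Bernoulli trials.  Fisher's exact test is used
    up to 1000 total occurrences (and always when an expected cell is below
    5), where it is cheap and the chi-squared approximation can drift by a
    few hundredths; the two-proportion chi-squared takes over for larger
    counts.  Both counts zero -> (nan, 1.0).
    """
    if length1 <= 0 or length2 <= 0:
        raise ValueError("region lengths must be positive")
    if count1 == 0 and count2 == 0:
        return float("nan"), 1.0
    d1, d2 = count1 / length1, count2 / length2
    ratio = d1 / d2 if d2 > 0 else float("inf")
    table = np.array([[count1, length1 - count1],
                      [count2, length2 - count2]], dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if count1 + count2 <= 1000 or (expected < 5).any():
        p = float(stats.fisher_exact(table.astype(int))[1])
    else:
        chi2 = stats.chi2_contingency(table, correction=False)[0]
        p = float(stats.chi2.sf(chi2, 1))
    return ratio, p


def expected_count(pattern: str, seq: str) -> float:
    """Expected double-strand occurrences under the region's base composition.

    A mononucleotide model: per window, the product over pattern positions
    of the summed frequencies of the bases each code accepts, times the
    number of windows, summed over both orientations.
    """
    seq = seq.upper()
    L = len(seq)
    k = len(pattern)
    if L < k:
        return 0.0
    freqs = {b: seq.count(b) / L for b in "ACGT"}

    def one_strand(pat: str) -> float:
        prob = 1.0
        for c in pat:
            prob *= sum(freqs[b] for b in IUPAC_SETS[c])
        return prob * (L - k + 1)

    return one_strand(pattern) + one_strand(reverse_complement(pattern))


def observed_expected_ratio(count: int, pattern: str, seq: str) -> float:
    """Observed / composition-expected occurrence ratio for one region."""
    exp = expected_count(pattern, seq)
    return count / exp if exp > 0 else float("nan")


def host_remainder(contig_length: int, prophages: list[Region]) -> int:
    """Length of the contig minus all prophage intervals."""
    return contig_length - sum(len(r) for r in prophages)


def region_densities(contigs: dict[str, str], regions: list[Region],
                     motifs: list[Motif]) -> pd.DataFrame:
    """Per-motif densities inside each region and in each host remainder.

    Occurrence counts are double-strand (each strand occurrence counted),
    with the single-strand plus-orientation count reported alongside, since
    published spacing figures do not always state the convention.
    """
    import re as _re
    from .motif_model import iupac_to_regex

    rows = []
    by_contig: dict[str, list[Region]] = {}
    for r in regions:
        by_contig.setdefault(r.contig, []).append(r)
    for contig, contig_regions in by_contig.items():
        seq = contigs[contig]
        spans = {"host_remainder": None}
        for region in contig_regions:
            spans[region.label] = (region.start, region.end)
        for motif in motifs:
            for label, span in spans.items():
                if span is None:
                    sub = seq
                    for region in contig_regions:
                        sub = sub[:region.start] + "N" * len(region) \
                            + sub[region.end:]
                    length = host_remainder(len(seq), contig_regions)
                else:
                    sub = seq[span[0]:span[1]]
                    length = span[1] - span[0]
                n_both = count_occurrences(sub, motif.iupac)
                n_plus = len(_re.findall(
                    "(?=" + iupac_to_regex(motif.iupac) + ")", sub))
                res = motif_density(n_both, length, motif.bracketed, label)
                rows.append({
                    "contig": contig, "motif": motif.bracketed,
                    "region": label, "count_both_strands": n_both,
                    "count_plus_strand": n_plus, "length_bp": length,
                    "density_per_bp": res.density_per_bp,
                    "spacing_bp": res.spacing_bp,
                    "spacing_exact": res.spacing_exact,
                    "obs_exp": observed_expected_ratio(n_both, motif.iupac,
                                                       sub.replace("N", "")
                                                       if span is None
                                                       else sub),
                })
    return pd.DataFrame(rows)


@dataclass
class HostMatch:
    phage_id: str
    host_id: str
    shared_motifs: tuple[str, ...]
    score: float


def _motif_str(m) -> str:
    return m.iupac if isinstance(m, Motif) else str(m).upper()


def match_hosts(phage_profiles: dict[str, set],
                host_rm_sets: dict[str, set],
                weight: str = "uniform") -> list[HostMatch]:
    """Rank candidate hosts for each phage by motif-profile overlap.

    A phage motif and a host recognition motif match when either IUPAC
    pattern subsumes the other in either orientation.  The score is a
    weighted Jaccard index: matched weight over total weight of both sets
    (1 for identical recognition repertoires, 0 for disjoint ones).
    ``weight`` is "uniform" or "information" (pattern information content
    in bits).  Ties rank by host id.
    """
    if weight not in ("uniform", "information"):
        raise ValueError(f"unknown weight scheme {weight!r}")

    def w(pattern: str) -> float:
        return information_bits(pattern) if weight == "information" else 1.0

    matches: list[HostMatch] = []
    for phage_id, phage_motifs in phage_profiles.items():
        pm = sorted({_motif_str(m) for m in phage_motifs})
        if not pm:
            logger.info("phage %s has an empty motif profile", phage_id)
            continue
        ranked = []
        for host_id, host_motifs in host_rm_sets.items():
            hm = sorted({_motif_str(m) for m in host_motifs})
            matched_p = [m for m in pm if any(motifs_match(m, h) for h in hm)]
            matched_h = [h for h in hm if any(motifs_match(h, m) for m in pm)]
            total = sum(w(m) for m in pm) + sum(w(h) for h in hm)
            matched = sum(w(m) for m in matched_p) + sum(w(h)
                                                         for h in matched_h)
            score = matched / total if total > 0 else 0.0
            shared = tuple(sorted(set(matched_p) | set(matched_h)))
            ranked.append(HostMatch(phage_id, host_id, shared, score))
        ranked.sort(key=lambda h: (-h.score, h.host_id))
        matches.extend(ranked)
    return matches


def host_match_report(matches: list[HostMatch]) -> pd.DataFrame:
    return pd.DataFrame([{
        "phage_id": m.phage_id, "host_id": m.host_id,
        "score": m.score, "shared_motifs": ",".join(m.shared_motifs) or ".",
    } for m in matches], columns=["phage_id", "host_id", "score",
                                  "shared_motifs"])
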