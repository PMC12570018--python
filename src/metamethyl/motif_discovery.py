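"""De novo methylation-motif discovery by k-mer enrichment.

The algorithm is deliberately simple and fully deterministic:

1. collect *seed sites* — positions whose (pooled) methylation fraction is
   in the "high" category (> 66%) at adequate coverage — and extract the
   sequence context around each, reverse-complementing minus-strand
   contexts so the methylated base always sits at a fixed index;
2. for every sub-window of length k <= k_max that contains the methylated
   position, count each concrete k-mer among seed contexts and in the whole
   contig (both strands, the empirical background);
3. test enrichment of each k-mer with a 2x2 chi-squared (no continuity
   correction) and control the FDR across candidates (Benjamini-Hochberg);
4. greedily generalise the most significant concrete k-mer by merging
   Hamming-distance-1 siblings whose enrichment rate reaches a fraction of
   the parent's, rewriting merged positions as the minimal IUPAC code;
5. trim flanking positions that become N and drop candidates whose seed
   sites are already explained by a reported motif.

The empirical background (the contig's own k-mer counts) makes the test
robust to GC and composition skew.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .methylome_profile import DEFAULT_MIN_COV
from .motif_model import (Motif, iupac_match, minimal_code,
                          reverse_complement)

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
CANONICAL_BASE = {"6mA": "A", "5mC": "C", "4mC": "C"}


def select_seed_sites(records: pd.DataFrame,
                      min_cov: int = DEFAULT_MIN_COV,
                      min_fraction: float = 0.66) -> dict[str, pd.DataFrame]:
    """Highly methylated sites per modification type.

    Counts are pooled across samples per (contig, pos, strand, mod_type);
    a site is a seed when pooled coverage >= min_cov and pooled fraction
    strictly exceeds min_fraction (the "high" category threshold).
    Returns one (contig, pos, strand) frame per modification type.
    """
    out: dict[str, pd.DataFrame] = {}
    if not len(records):
        return out
    pooled = (records.groupby(["mod_type", "contig", "pos", "strand"],
                              sort=True)[["valid_cov", "n_mod"]]
              .sum().reset_index())
    pooled = pooled[pooled["valid_cov"] >= min_cov]
    pooled = pooled[pooled["n_mod"] / pooled["valid_cov"] > min_fraction]
    for mod_type, sub in pooled.groupby("mod_type"):
        out[mod_type] = sub[["contig", "pos", "strand"]].reset_index(drop=True)
    return out


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def _kmer_counts(codes: np.ndarray, k: int) -> np.ndarray:
    """Occurrence count of every concrete k-mer (4**k bins) in one strand."""
    L = len(codes)
    if L < k:
        return np.zeros(4 ** k, dtype=np.int64)
    n_win = L - k + 1
    vals = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for i in range(k):
        col = codes[i:i + n_win]
        valid &= col >= 0
        vals = vals * 4 + np.where(col >= 0, col, 0)
    return np.bincount(vals[valid], minlength=4 ** k)


class BackgroundModel:
    """Empirical k-mer counts of a contig, both strands."""

    def __init__(self, seq: str, k_max: int):
        seq = seq.upper()
        fwd = _encode(seq)
        rev = _encode(reverse_complement(seq))
        self._counts = {k: _kmer_counts(fwd, k) + _kmer_counts(rev, k)
                        for k in range(1, k_max + 1)}
        self._totals = {k: 2 * max(len(seq) - k + 1, 0)
                        for k in range(1, k_max + 1)}

    def count(self, kmer: str) -> int:
        idx = 0
        for c in kmer:
            idx = idx * 4 + _BASE_INDEX[c]
        return int(self._counts[len(kmer)][idx])

    def total(self, k: int) -> int:
        return self._totals[k]


@dataclass
class CandidateMotif:
    """A reported motif with the enrichment statistics of its seed k-mer."""

    motif: Motif
    n_meth_sites_matching: int
    n_background_matching: int
    chi2: float
    p_raw: float
    p_adj: float


def _chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    """Pearson chi-squared of [[a, b], [c, d]] without continuity correction."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def _extract_contexts(seq: str, sites: pd.DataFrame, flank: int,
                      mod_type: str) -> list[tuple[str, int]]:
    """(context, site_index) pairs with the methylated base at index flank."""
    L = len(seq)
    canonical = CANONICAL_BASE[mod_type]
    contexts = []
    for i, (pos, strand) in enumerate(zip(sites["pos"], sites["strand"])):
        pos = int(pos)
        if pos - flank < 0 or pos + flank + 1 > L:
            continue
        window = seq[pos - flank:pos + flank + 1]
        if strand == "-":
            window = reverse_complement(window)
        if window[flank] != canonical:   # record disagrees with the sequence
            continue
        contexts.append((window, i))
    return contexts


def discover_motifs(seq: str,
                    records: pd.DataFrame,
                    k_max: int = 6,
                    flank: int = 5,
                    alpha: float = 0.01,
                    min_sites: int = 20,
                    min_cov: int = DEFAULT_MIN_COV,
                    min_fraction: float = 0.66,
                    support_frac: float = 0.5,
                    min_seed_count: int = 3,
                    contig: str | None = None) -> list[CandidateMotif]:
    """Discover methylation motifs on one contig.

    ``records`` are that contig's per-site methylation calls (any number of
    samples; counts are pooled).  Returns maximal non-redundant motifs per
    modification type, most significant first.  Fewer than ``min_sites``
    seed sites for a modification type yields no motifs for that type.
    """
    seq = seq.upper()
    if len(seq) < 2 * flank + 1:
        raise ValueError("sequence shorter than the context window")
    if contig is not None:
        records = records[records["contig"] == contig]
    seeds_by_type = select_seed_sites(records, min_cov, min_fraction)
    background = BackgroundModel(seq, k_max)
    reported: list[CandidateMotif] = []
    for mod_type in sorted(seeds_by_type):
        sites = seeds_by_type[mod_type]
        if len(sites) < min_sites:
            logger.info("%s: %d seed sites < %d, skipping discovery",
                        mod_type, len(sites), min_sites)
            continue
        reported.extend(_discover_for_type(
            seq, sites, mod_type, background, k_max, flank, alpha,
            min_sites, support_frac, min_seed_count))
    reported.sort(key=lambda c: (-c.chi2, c.motif.iupac))
    return reported


def _discover_for_type(seq, sites, mod_type, background, k_max, flank,
                       alpha, min_sites, support_frac,
                       min_seed_count) -> list[CandidateMotif]:
    contexts = _extract_contexts(seq, sites, flank, mod_type)
    if len(contexts) < min_sites:
        logger.info("%s: %d usable contexts < %d, skipping",
                    mod_type, len(contexts), min_sites)
        return []
    n_ctx = len(contexts)
    width = 2 * flank + 1

    # slot = (window start within context, k); every slot covers the center
    slots = [(s, k) for k in range(1, k_max + 1)
             for s in range(max(0, flank - k + 1),
                            min(flank, width - k) + 1)]
    slot_counts: dict[tuple[int, int], Counter] = {}
    for s, k in slots:
        ctr: Counter = Counter()
        for window, _ in contexts:
            kmer = window[s:s + k]
            if "N" not in kmer:
                ctr[kmer] += 1
        slot_counts[(s, k)] = ctr

    # enrichment test per concrete k-mer per slot
    cand = []   # (slot, kmer, n_seed, n_bg, chi2, p)
    for (s, k), ctr in slot_counts.items():
        n_bg_total = background.total(k)
        for kmer, n_seed in ctr.items():
            if n_seed < min_seed_count:
                continue
            n_bg = background.count(kmer)
            # enrichment only: observed seed rate must exceed background rate
            if n_seed / n_ctx <= n_bg / n_bg_total:
                continue
            chi2 = _chi2_2x2(n_seed, n_ctx - n_seed,
                             n_bg, n_bg_total - n_bg)
            p = float(stats.chi2.sf(chi2, 1))
            cand.append(((s, k), kmer, n_seed, n_bg, chi2, p))
    if not cand:
        return []
    from .differential import bh_adjust
    p_adj = bh_adjust([c[5] for c in cand])
    sig = [c + (float(a),) for c, a in zip(cand, p_adj) if a <= alpha]
    # determinism: chi2 desc, then seed count desc, then lexicographic
    sig.sort(key=lambda c: (-c[4], -c[2], c[1]))

    results: list[CandidateMotif] = []
    explained: list[set[int]] = []
    seen_patterns: set[tuple[str, int]] = set()
    for (s, k), kmer, n_seed, n_bg, chi2, p, padj in sig:
        pattern = _generalise(kmer, s, flank, slot_counts[(s, k)],
                              background, support_frac)
        pattern, offset = _trim_n(pattern, flank - s)
        if (pattern, offset) in seen_patterns:
            continue
        matched = {idx for window, idx in contexts
                   if iupac_match(pattern,
                                  window[flank - offset:
                                         flank - offset + len(pattern)])}
        if any(matched <= prev for prev in explained):
            continue  # redundant: an already-reported motif explains it
        seen_patterns.add((pattern, offset))
        explained.append(matched)
        n_bg_pattern = _pattern_background(pattern, background)
        motif = Motif(pattern, offset, mod_type)
        results.append(CandidateMotif(motif, len(matched), n_bg_pattern,
                                      chi2, p, padj))
    return results


def _generalise(kmer: str, slot_start: int, flank: int, ctr: Counter,
                background: BackgroundModel, support_frac: float) -> str:
    """Merge Hamming-1 siblings position by position into IUPAC codes."""
    center = flank - slot_start
    parent_bg = background.count(kmer)
    parent_rate = ctr[kmer] / parent_bg if parent_bg else float("inf")
    codes = []
    for i, base in enumerate(kmer):
        if i == center:
            codes.append(base)   # the methylated base itself is never merged
            continue
        merged = {base}
        for alt in "ACGT":
            if alt == base:
                continue
            sib = kmer[:i] + alt + kmer[i + 1:]
            n_sib = ctr.get(sib, 0)
            if n_sib == 0:
                continue
            bg_sib = background.count(sib)
            sib_rate = n_sib / bg_sib if bg_sib else float("inf")
            if sib_rate >= support_frac * parent_rate:
                merged.add(alt)
        codes.append(minimal_code(merged))
    return "".join(codes)


def _trim_n(pattern: str, offset: int) -> tuple[str, int]:
    """Strip leading/trailing N positions, keeping the methylated offset."""
    start, end = 0, len(pattern)
    while start < offset and pattern[start] == "N":
        start += 1
    while end - 1 > offset and pattern[end - 1] == "N":
        end -= 1
    return pattern[start:end], offset - start


def _pattern_background(pattern: str, background: BackgroundModel) -> int:
    """Double-strand background count of a (possibly degenerate) pattern."""
    from itertools import product
    from .motif_model import IUPAC_SETS
    sets = [sorted(IUPAC_SETS[c]) for c in pattern]
    n_concrete = 1
    for s in sets:
        n_concrete *= len(s)
    if n_concrete > 4096:   # too degenerate to enumerate; report -1
        return -1
    return sum(background.count("".join(bases))
               for bases in product(*sets))


def discovery_report(candidates: list[CandidateMotif],
                     contig: str) -> pd.DataFrame:
    rows = [{
        "contig": contig,
        "motif": c.motif.bracketed,
        "iupac": c.motif.iupac,
        "mod_type": c.motif.mod_type,
        "offset": c.motif.meth_offset,
        "n_sites": c.n_meth_sites_matching,
        "n_background": c.n_background_matching,
        "chi2": c.chi2,
        "p_raw": c.p_raw,
        "p_adj": c.p_adj,
    } for c in candidates]
    return pd.DataFrame(rows, columns=[
        "contig", "motif", "iupac", "mod_type", "offset", "n_sites",
        "n_background", "chi2", "p_raw", "p_adj"])
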