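"""Synthetic input bundles with known ground truth.

Emulates the statistical structure of a nanopore community methylome
experiment: contigs with planted IUPAC methylation motifs, two sample
groups ("top"/"bottom" ice horizons) with replicate samples, per-site true
methylation fractions drawn from a Beta distribution (concentration 50,
giving overdispersion comparable to real pileups), Poisson coverage with
Binomial modified-read counts, a controlled differentially methylated
subset of instances, a motif-depleted prophage region, gene models with
promoters, and a restriction-modification gene table with a controlled
MTase/REase imbalance.

One global seed drives independent named substreams (sequence, fractions,
coverage, ...) so that changing one parameter perturbs only its own stream,
and the same config + seed always produces a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .io_formats import GeneRecord, Region, RMGene
from .motif_model import (IUPAC_SETS, Motif, iupac_match,
                          reverse_complement, scan_motif)

GROUPS = ("top", "bottom")

#: recognition motifs used for complete (non-orphan) RM operons, chosen not
#: to collide with the default planted motif
PAIRED_SYSTEM_MOTIFS = {"I": "ACAYNNNNNRTT", "II": "GGCC", "III": "AAGACC"}


@dataclass(frozen=True)
class PlantedMotif:
    motif: Motif
    site_fraction_mean: float
    background_fraction_mean: float
    min_instances: int = 0   # up-sample by targeted insertion below this

    def __post_init__(self):
        for f in (self.site_fraction_mean, self.background_fraction_mean):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def default_planted_motifs() -> list[PlantedMotif]:
    return [PlantedMotif(Motif("GATC", 1, "6mA"), 0.8, 0.02)]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_contigs: int = 2
    contig_length_bp: int = 100_000
    gc_fraction: float = 0.40
    planted_motifs: list[PlantedMotif] = field(
        default_factory=default_planted_motifs)
    n_samples_per_group: int = 3
    coverage_lambda: float = 30.0
    diff_fraction_of_instances: float = 0.2
    diff_delta: float = 0.3
    beta_concentration: float = 50.0
    prophage: tuple[int, float] | None = (30_000, 0.5)  # (length, rho)
    genes: tuple[int, int] = (60, 900)                  # (n, mean length)
    # system type -> (n orphan MTases, n lone REases, n complete operons)
    rm_table_spec: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: {"I": (2, 1, 1), "II": (4, 1, 1),
                                 "III": (1, 0, 1), "IV": (0, 1, 0)})
    ori_frac: float | None = None   # plant a GC-skew ori at this fraction
    skew_amplitude: float = 0.03
    groups: tuple[str, str] = GROUPS

    def validate(self) -> None:
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")
        if not 0.0 <= self.diff_fraction_of_instances <= 1.0:
            raise ValueError("diff_fraction_of_instances must be in [0, 1]")
        if not -1.0 <= self.diff_delta <= 1.0:
            raise ValueError("diff_delta must be in [-1, 1]")
        if self.prophage is not None:
            length, rho = self.prophage
            if length >= self.contig_length_bp:
                raise ValueError("prophage longer than its contig")
            if not 0.0 <= rho <= 1.0:
                raise ValueError("prophage depletion rho must be in [0, 1]")
        for t, spec in self.rm_table_spec.items():
            if t == "IV" and (spec[0] or spec[2]):
                raise ValueError("Type IV systems cannot carry MTases")

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "planted_motifs" in data:
            planted = []
            for item in data["planted_motifs"]:
                planted.append(PlantedMotif(
                    Motif(item["iupac"], item["meth_offset"],
                          item["mod_type"]),
                    item["site_fraction_mean"],
                    item["background_fraction_mean"],
                    item.get("min_instances", 0)))
            data["planted_motifs"] = planted
        for key in ("prophage", "genes", "groups"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        if "rm_table_spec" in data:
            data["rm_table_spec"] = {k: tuple(v) for k, v
                                     in data["rm_table_spec"].items()}
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_motifs"] = [{
            "iupac": p.motif.iupac, "meth_offset": p.motif.meth_offset,
            "mod_type": p.motif.mod_type,
            "site_fraction_mean": p.site_fraction_mean,
            "background_fraction_mean": p.background_fraction_mean,
            "min_instances": p.min_instances,
        } for p in self.planted_motifs]
        return d


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG stream derived from seed + purpose."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def random_sequence(length: int, gc: float,
                    rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=probs))


def skewed_sequence(length: int, ori: int, gc: float, amplitude: float,
                    rng: np.random.Generator) -> str:
    """Sequence with leading-strand G excess on [ori, ter), circularly.

    ter sits half a genome downstream of ori.  Between ori and ter G is
    over-represented by ``amplitude`` (and C under-represented); the
    relationship reverses on the other replichore, producing a cumulative
    GC-skew minimum at ori and maximum at ter.
    """
    ter = (ori + length // 2) % length
    pos = np.arange(length)
    if ori <= ter:
        leading = (pos >= ori) & (pos < ter)
    else:
        leading = (pos >= ori) | (pos < ter)
    at = (1 - gc) / 2
    bases = np.array(list("ACGT"))
    p_lead = [at, gc / 2 - amplitude * gc / 2, gc / 2 + amplitude * gc / 2, at]
    p_lag = [at, gc / 2 + amplitude * gc / 2, gc / 2 - amplitude * gc / 2, at]
    seq = np.where(leading,
                   rng.choice(bases, size=length, p=p_lead),
                   rng.choice(bases, size=length, p=p_lag))
    return "".join(seq)


def _beta_draw(mean: float, concentration: float, size,
               rng: np.random.Generator) -> np.ndarray:
    if mean <= 0.0:
        return np.zeros(size)
    if mean >= 1.0:
        return np.ones(size)
    a = mean * concentration
    b = (1 - mean) * concentration
    return rng.beta(a, b, size=size)


def _ablate_instance(seq_list: list[str], inst, motif: Motif) -> None:
    """Break one motif occurrence by substituting a non-methylated base.

    Never touches the methylated base of either strand's reading of the
    window; tries deterministic substitutions until the window no longer
    matches the motif in either orientation.
    """
    k = len(motif)
    protected = {motif.meth_offset, k - 1 - motif.meth_offset}
    window_start = inst.start
    for i in range(k):
        if i in protected:
            continue
        original = seq_list[window_start + i]
        for sub in "ACGT":
            if sub == original:
                continue
            seq_list[window_start + i] = sub
            window = "".join(seq_list[window_start:window_start + k])
            if (not iupac_match(motif.iupac, window) and
                    not iupac_match(reverse_complement(motif.iupac), window)):
                return
        seq_list[window_start + i] = original
    raise RuntimeError("could not ablate motif occurrence")  # pragma: no cover


@dataclass
class SimBundle:
    config: SimulationConfig
    contigs: dict[str, str]
    records: pd.DataFrame          # all samples, io_formats.RECORD_COLUMNS
    sample_groups: dict[str, str]  # sample id -> group label
    genes: list[GeneRecord]
    rm_genes: list[RMGene]
    regions: list[Region]
    truth: dict                    # instances frame, prophage, ori, orphans


def simulate(config: SimulationConfig) -> SimBundle:
    """Generate a complete in-memory bundle with ground truth."""
    config.validate()
    seed = config.seed
    contigs: dict[str, str] = {}
    rng_seq = substream(seed, "sequence")
    for i in range(config.n_contigs):
        name = f"ctg{i:03d}"
        if i == 0 and config.ori_frac is not None:
            ori = int(config.ori_frac * config.contig_length_bp)
            contigs[name] = skewed_sequence(
                config.contig_length_bp, ori, config.gc_fraction,
                config.skew_amplitude, rng_seq)
        else:
            contigs[name] = random_sequence(
                config.contig_length_bp, config.gc_fraction, rng_seq)

    # up-sample planted motifs to a floor count by targeted insertion
    rng_plant = substream(seed, "planting")
    inserted: list[dict] = []
    for planted in config.planted_motifs:
        if planted.min_instances <= 0:
            continue
        for name in contigs:
            seq = contigs[name]
            have = len(scan_motif(seq, planted.motif, name))
            need = planted.min_instances - have
            if need <= 0:
                continue
            seq_list = list(seq)
            k = len(planted.motif)
            concrete = "".join(sorted(IUPAC_SETS[c])[0]
                               for c in planted.motif.iupac)
            for _ in range(need):
                pos = int(rng_plant.integers(0, len(seq_list) - k))
                seq_list[pos:pos + k] = concrete
                inserted.append({"contig": name, "start": pos,
                                 "motif": planted.motif.iupac})
            contigs[name] = "".join(seq_list)

    # prophage: carve a region from the first contig and ablate planted
    # motif occurrences down to a fraction rho of their density
    regions: list[Region] = []
    prophage_truth = None
    rng_phage = substream(seed, "prophage")
    if config.prophage is not None and config.planted_motifs:
        length, rho = config.prophage
        name = next(iter(contigs))
        start = int(rng_phage.integers(0, config.contig_length_bp - length))
        region = Region(name, start, start + length, "prophage")
        regions.append(region)
        seq_list = list(contigs[name])
        n_ablated = 0
        for planted in config.planted_motifs:
            insts = [inst for inst
                     in scan_motif(contigs[name], planted.motif, name)
                     if inst.strand == "+"   # one ablation kills both strands
                     and region.start <= inst.start
                     and inst.start + len(planted.motif) <= region.end]
            keep = rng_phage.random(len(insts)) < rho
            for inst, kept in zip(insts, keep):
                if not kept:
                    _ablate_instance(seq_list, inst, planted.motif)
                    n_ablated += 1
        contigs[name] = "".join(seq_list)
        prophage_truth = {"contig": name, "start": region.start,
                          "end": region.end, "rho": rho,
                          "n_ablated": n_ablated}

    # final instance truth from the final sequences
    inst_rows = []
    site_index: dict[tuple, int] = {}
    for planted in config.planted_motifs:
        for name, seq in contigs.items():
            for inst in scan_motif(seq, planted.motif, name):
                key = (name, inst.site_pos, inst.strand,
                       planted.motif.mod_type)
                if key in site_index:
                    continue
                site_index[key] = len(inst_rows)
                inst_rows.append({
                    "contig": name, "strand": inst.strand,
                    "start": inst.start, "site_pos": inst.site_pos,
                    "motif": planted.motif.iupac,
                    "mod_type": planted.motif.mod_type,
                    "site_fraction_mean": planted.site_fraction_mean,
                    "in_prophage": bool(
                        prophage_truth is not None
                        and name == prophage_truth["contig"]
                        and prophage_truth["start"] <= inst.site_pos
                        < prophage_truth["end"]),
                })
    instances = pd.DataFrame(inst_rows)

    # true per-instance fractions per group, with a differential subset
    rng_frac = substream(seed, "fractions")
    group_a, group_b = config.groups
    n_inst = len(instances)
    if n_inst:
        true_a = np.empty(n_inst)
        true_b = np.empty(n_inst)
        for mean in instances["site_fraction_mean"].unique():
            mask = (instances["site_fraction_mean"] == mean).to_numpy()
            true_a[mask] = _beta_draw(mean, config.beta_concentration,
                                      int(mask.sum()), rng_frac)
            true_b[mask] = _beta_draw(mean, config.beta_concentration,
                                      int(mask.sum()), rng_frac)
        n_diff = int(round(config.diff_fraction_of_instances * n_inst))
        diff_idx = rng_frac.choice(n_inst, size=n_diff, replace=False)
        is_diff = np.zeros(n_inst, dtype=bool)
        is_diff[diff_idx] = True
        true_b = np.where(is_diff,
                          np.clip(true_b + config.diff_delta, 0.0, 1.0),
                          true_b)
        instances[f"true_fraction_{group_a}"] = true_a
        instances[f"true_fraction_{group_b}"] = true_b
        instances["is_diff"] = is_diff

    records = _simulate_records(config, contigs, instances, site_index)

    genes = _simulate_genes(config, contigs)
    rm_genes, orphan_truth = _simulate_rm_table(config)

    sample_groups = {}
    for g in config.groups:
        for i in range(1, config.n_samples_per_group + 1):
            sample_groups[f"{g}_{i}"] = g

    truth = {
        "instances": instances,
        "inserted": inserted,
        "prophage": prophage_truth,
        "ori_bp": (int(config.ori_frac * config.contig_length_bp)
                   if config.ori_frac is not None else None),
        "expected_orphans": orphan_truth,
    }
    return SimBundle(config, contigs, records, sample_groups, genes,
                     rm_genes, regions, truth)


def _simulate_records(config, contigs, instances, site_index) -> pd.DataFrame:
    """Per-sample per-site pileup records for every canonical-base site."""
    from .io_formats import RECORD_COLUMNS

    group_a, group_b = config.groups
    mod_types = sorted({p.motif.mod_type for p in config.planted_motifs})
    background_mean = {p.motif.mod_type: p.background_fraction_mean
                       for p in config.planted_motifs}
    rng_bg = substream(config.seed, "background")
    rng_cov = substream(config.seed, "coverage")

    frames = []
    for mod_type in mod_types:
        plus_base = "A" if mod_type == "6mA" else "C"
        minus_base = "T" if mod_type == "6mA" else "G"
        for name, seq in contigs.items():
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            pos_plus = np.flatnonzero(arr == ord(plus_base))
            pos_minus = np.flatnonzero(arr == ord(minus_base))
            pos = np.concatenate([pos_plus, pos_minus])
            strand = np.concatenate([np.full(len(pos_plus), "+"),
                                     np.full(len(pos_minus), "-")])
            order = np.argsort(pos, kind="stable")
            pos, strand = pos[order], strand[order]
            n_sites = len(pos)
            frac_a = _beta_draw(background_mean[mod_type],
                                config.beta_concentration, n_sites, rng_bg)
            frac_b = _beta_draw(background_mean[mod_type],
                                config.beta_concentration, n_sites, rng_bg)
            # overwrite planted instance sites with their true fractions
            if len(instances):
                for i, (p, s) in enumerate(zip(pos, strand)):
                    idx = site_index.get((name, int(p), s, mod_type))
                    if idx is not None:
                        frac_a[i] = instances[f"true_fraction_{group_a}"].iat[idx]
                        frac_b[i] = instances[f"true_fraction_{group_b}"].iat[idx]
            for group, frac in ((group_a, frac_a), (group_b, frac_b)):
                for rep in range(1, config.n_samples_per_group + 1):
                    sample = f"{group}_{rep}"
                    cov = rng_cov.poisson(config.coverage_lambda, n_sites)
                    nmod = rng_cov.binomial(cov, frac)
                    keep = cov > 0
                    frames.append(pd.DataFrame({
                        "sample": sample,
                        "contig": name,
                        "pos": pos[keep],
                        "strand": strand[keep],
                        "mod_type": mod_type,
                        "valid_cov": cov[keep],
                        "n_mod": nmod[keep],
                        "fraction": nmod[keep] / cov[keep],
                    }))
    if not frames:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.concat(frames, ignore_index=True)[RECORD_COLUMNS]


def _simulate_genes(config, contigs) -> list[GeneRecord]:
    """Non-overlapping gene models placed uniformly, strands Bernoulli(1/2)."""
    rng = substream(config.seed, "genes")
    n_genes, mean_len = config.genes
    genes: list[GeneRecord] = []
    if n_genes <= 0:
        return genes
    names = list(contigs)
    counter = 0
    for name in names:
        quota = n_genes // len(names) + (1 if name == names[0]
                                         and n_genes % len(names) else 0)
        occupied: list[tuple[int, int]] = []
        attempts = 0
        L = len(contigs[name])
        while len(occupied) < quota and attempts < quota * 50:
            attempts += 1
            length = max(300, int(rng.normal(mean_len, mean_len / 4)))
            if length >= L:
                continue
            start = int(rng.integers(0, L - length))
            end = start + length
            if any(start < e and s < end for s, e in occupied):
                continue
            occupied.append((start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(name, start, end, strand,
                                    f"gene_{counter:05d}", "hypothetical"))
            counter += 1
        genes.sort(key=lambda g: (g.contig, g.start))
    return genes


def _simulate_rm_table(config) -> tuple[list[RMGene], dict[str, int]]:
    """RM gene table with a controlled per-type MTase/REase imbalance.

    Orphan MTases get a planted motif and sit alone on their own pseudo
    contig; lone REases have unknown motifs far from any MTase; complete
    operons pair an MTase and REase with a shared (non-planted) motif at
    adjacent coordinates.  Expected orphan count per type is therefore the
    first element of the spec tuple.
    """
    rng = substream(config.seed, "rm_table")
    planted_motifs = [p.motif.iupac for p in config.planted_motifs] or ["GATC"]
    genes: list[RMGene] = []
    expected_orphans: dict[str, int] = {}
    gid = 0
    for sys_type, (n_mtase, n_rease, n_paired) in sorted(
            config.rm_table_spec.items()):
        expected_orphans[sys_type] = n_mtase
        for i in range(n_mtase):
            motif = planted_motifs[i % len(planted_motifs)]
            genes.append(RMGene(
                contig=f"rm_ctg_{sys_type}_{gid}", gene_id=f"rm_{gid:04d}",
                system_type=sys_type, role="MTase",
                recognition_motif=motif, methylated_offset=1,
                homolog_identity=round(80 + 19 * float(rng.random()), 2),
                start=1000, end=2000, genome="sim_genome"))
            gid += 1
        for _ in range(n_rease):
            genes.append(RMGene(
                contig=f"rm_ctg_{sys_type}_{gid}", gene_id=f"rm_{gid:04d}",
                system_type=sys_type, role="REase",
                recognition_motif=None,
                homolog_identity=round(60 + 39 * float(rng.random()), 2),
                start=1000, end=2000, genome="sim_genome"))
            gid += 1
        pair_motif = PAIRED_SYSTEM_MOTIFS.get(sys_type, "GGCC")
        for _ in range(n_paired):
            base = f"rm_ctg_{sys_type}_{gid}"
            genes.append(RMGene(
                contig=base, gene_id=f"rm_{gid:04d}", system_type=sys_type,
                role="MTase", recognition_motif=pair_motif,
                methylated_offset=0,
                homolog_identity=round(80 + 19 * float(rng.random()), 2),
                start=1000, end=2000, genome="sim_genome"))
            gid += 1
            genes.append(RMGene(
                contig=base, gene_id=f"rm_{gid:04d}", system_type=sys_type,
                role="REase", recognition_motif=pair_motif,
                homolog_identity=round(80 + 19 * float(rng.random()), 2),
                start=2100, end=3100, genome="sim_genome"))
            gid += 1
    return genes, expected_orphans


def simulate_instance_profiles(n_instances: int = 100,
                               site_fraction_mean: float = 0.8,
                               n_samples_per_group: int = 3,
                               coverage_lambda: float = 30.0,
                               diff_fraction: float = 0.0,
                               diff_delta: float = 0.0,
                               beta_concentration: float = 50.0,
                               rng: np.random.Generator | None = None,
                               contig: str = "ctg000",
                               groups: tuple[str, str] = GROUPS):
    """Instance profiles for one contig under the generator's noise model.

    A fast path to the observation model (independent per-group Beta true
    fractions, Poisson coverage, Binomial modified counts) that skips
    sequence synthesis: instances are laid out on a virtual contig.  Used
    for calibrating the differential tests, where only the per-instance
    group statistics matter.
    """
    from .methylome_profile import InstanceProfile
    from .motif_model import Motif, MotifInstance

    if rng is None:
        rng = np.random.default_rng(0)
    group_a, group_b = groups
    motif = Motif("GATC", 1, "6mA")
    conc = beta_concentration
    true_a = _beta_draw(site_fraction_mean, conc, n_instances, rng)
    true_b = _beta_draw(site_fraction_mean, conc, n_instances, rng)
    n_diff = int(round(diff_fraction * n_instances))
    if n_diff:
        idx = rng.choice(n_instances, size=n_diff, replace=False)
        true_b[idx] = np.clip(true_b[idx] + diff_delta, 0.0, 1.0)
    profiles = []
    for i in range(n_instances):
        inst = MotifInstance(contig, "+", 10 * i, 10 * i + 1, motif)
        per_sample: dict[str, tuple[int, int, float]] = {}
        counts = {group_a: [0, 0], group_b: [0, 0]}
        fracs = {group_a: [], group_b: []}
        for group, true in ((group_a, true_a[i]), (group_b, true_b[i])):
            for rep in range(1, n_samples_per_group + 1):
                cov = int(rng.poisson(coverage_lambda))
                if cov == 0:
                    continue
                nmod = int(rng.binomial(cov, true))
                per_sample[f"{group}_{rep}"] = (cov, nmod, nmod / cov)
                counts[group][0] += cov
                counts[group][1] += nmod
                fracs[group].append(nmod / cov)
        prof = InstanceProfile(inst, per_sample)
        for group in (group_a, group_b):
            cov, nmod = counts[group]
            prof.group_counts[group] = (cov, nmod)
            prof.group_mean[group] = nmod / cov if cov else float("nan")
            f = fracs[group]
            prof.group_se[group] = (float(np.std(f, ddof=1) / np.sqrt(len(f)))
                                    if len(f) >= 2 else float("nan"))
        profiles.append(prof)
    return profiles


def simulate_depleted_contig(motif: Motif,
                             contig_length: int = 60_000,
                             prophage_length: int = 20_000,
                             rho: float = 0.5,
                             gc: float = 0.40,
                             rng: np.random.Generator | None = None,
                             name: str = "ctg000") -> tuple[str, Region]:
    """A contig whose prophage region is motif-depleted to density rho.

    Sequence-only fast path for density-comparison calibration: occurrences
    of ``motif`` inside the prophage are ablated (single-base substitution
    away from the methylated positions) with probability 1 - rho.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if prophage_length >= contig_length:
        raise ValueError("prophage longer than its contig")
    seq = random_sequence(contig_length, gc, rng)
    start = int(rng.integers(0, contig_length - prophage_length))
    region = Region(name, start, start + prophage_length, "prophage")
    seq_list = list(seq)
    insts = [inst for inst in scan_motif(seq, motif, name)
             if inst.strand == "+"
             and region.start <= inst.start
             and inst.start + len(motif) <= region.end]
    keep = rng.random(len(insts)) < rho
    for inst, kept in zip(insts, keep):
        if not kept:
            _ablate_instance(seq_list, inst, motif)
    return "".join(seq_list), region


def _write_bedmethyl(records: pd.DataFrame, path: Path) -> None:
    from .io_formats import MOD_TYPE_CODE
    with open(path, "w", newline="\n") as fh:
        df = records.sort_values(["contig", "pos", "strand"],
                                 kind="stable")
        for contig, pos, strand, mod, cov, nmod in zip(
                df["contig"], df["pos"], df["strand"], df["mod_type"],
                df["valid_cov"], df["n_mod"]):
            pct = 100.0 * nmod / cov
            fh.write("\t".join(map(str, [
                contig, pos, pos + 1, MOD_TYPE_CODE[mod], cov, strand,
                pos, pos + 1, "255,0,0", cov, f"{pct:.2f}", nmod,
                cov - nmod, 0, 0, 0, 0, 0])) + "\n")


def generate(config: SimulationConfig, out_dir: str | Path) -> SimBundle:
    """Simulate and write the full bundle + truth tables to ``out_dir``."""
    config.validate()   # fail before creating any file
    bundle = simulate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_formats.write_fasta(bundle.contigs, out / "contigs.fasta")
    for sample in bundle.sample_groups:
        _write_bedmethyl(bundle.records[bundle.records["sample"] == sample],
                         out / f"{sample}.bedmethyl")
    io_formats.write_gff(bundle.genes, out / "genes.gff3")
    io_formats.write_rm_table(bundle.rm_genes, out / "rm_genes.tsv")
    io_formats.write_regions(bundle.regions, out / "regions.bed")
    with open(out / "sample_groups.tsv", "w", newline="\n") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in bundle.sample_groups.items():
            fh.write(f"{sample}\t{group}\n")
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    if len(bundle.truth["instances"]):
        io_formats.write_report(bundle.truth["instances"],
                                truth_dir / "instances.tsv")
    meta = {k: v for k, v in bundle.truth.items() if k != "instances"}
    with open(truth_dir / "truth.json", "w", newline="\n") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(truth_dir / "config.json", "w", newline="\n") as fh:
        json.dump(config.to_jsonable(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return bundle
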