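"""Generator contracts: determinism, observation model, truth tables."""

import hashlib
import math
from pathlib import Path

import numpy as np
import pytest

from metamethyl.motif_model import Motif, count_occurrences, scan_motif
from metamethyl.synthetic_data import (PlantedMotif, SimulationConfig,
                                       generate, simulate,
                                       simulate_instance_profiles)


def _tiny_config(**kw):
    defaults = dict(
        seed=3, n_contigs=1, contig_length_bp=20_000,
        planted_motifs=[PlantedMotif(Motif("GATC", 1, "6mA"), 0.8, 0.02)],
        genes=(10, 500), prophage=(5_000, 0.5))
    defaults.update(kw)
    return SimulationConfig(**defaults)


def _dir_digest(path: Path) -> dict[str, str]:
    out = {}
    for p in sorted(path.rglob("*")):
        if p.is_file():
            out[str(p.relative_to(path))] = hashlib.sha256(
                p.read_bytes()).hexdigest()
    return out


class TestDeterminism:
    def test_same_seed_byte_identical_bundle(self, tmp_path):
        generate(_tiny_config(), tmp_path / "a")
        generate(_tiny_config(), tmp_path / "b")
        da, db = _dir_digest(tmp_path / "a"), _dir_digest(tmp_path / "b")
        assert da == db
        assert len(da) >= 10   # fasta + 6 bedmethyl + gff + rm + bed + truth

    def test_different_seed_differs(self, tmp_path):
        generate(_tiny_config(), tmp_path / "a")
        generate(_tiny_config(seed=4), tmp_path / "b")
        assert _dir_digest(tmp_path / "a") != _dir_digest(tmp_path / "b")


class TestObservationModel:
    def test_nmod_never_exceeds_coverage(self, small_bundle):
        recs = small_bundle.records
        assert (recs["n_mod"] <= recs["valid_cov"]).all()
        assert (recs["valid_cov"] > 0).all()

    def test_degenerate_limits(self):
        """site mean 1, background 0, high coverage: fractions are 0/1."""
        cfg = _tiny_config(
            contig_length_bp=5_000, prophage=None, genes=(0, 0),
            coverage_lambda=200.0, diff_fraction_of_instances=0.0,
            planted_motifs=[PlantedMotif(Motif("GATC", 1, "6mA"), 1.0, 0.0)])
        bundle = simulate(cfg)
        truth = bundle.truth["instances"]
        sites = set(zip(truth["contig"], truth["pos"]
                        if "pos" in truth else truth["site_pos"],
                        truth["strand"]))
        recs = bundle.records
        planted = [(c, p, s) in sites for c, p, s in
                   zip(recs["contig"], recs["pos"], recs["strand"])]
        planted = np.array(planted)
        assert (recs["fraction"][planted] == 1.0).all()
        assert (recs["fraction"][~planted] == 0.0).all()

    def test_natural_instance_count_matches_expectation(self):
        cfg = _tiny_config(contig_length_bp=500_000, gc_fraction=0.5,
                           prophage=None, genes=(0, 0))
        bundle = simulate(cfg)
        L = cfg.contig_length_bp
        expect = 2 * (L - 3) / 256
        n = len(bundle.truth["instances"])
        assert abs(n - expect) <= 3 * math.sqrt(expect)

    def test_differential_subset_size(self, small_bundle):
        truth = small_bundle.truth["instances"]
        frac = truth["is_diff"].mean()
        assert frac == pytest.approx(0.2, abs=0.01)

    def test_prophage_depletion_in_truth(self, small_bundle):
        truth = small_bundle.truth["instances"]
        prophage = small_bundle.truth["prophage"]
        inside = truth["in_prophage"].sum()
        p_len = prophage["end"] - prophage["start"]
        host_len = small_bundle.config.contig_length_bp - p_len
        outside = len(truth) - inside
        # planted density inside ~ rho * density outside
        ratio = (inside / p_len) / (outside / host_len)
        assert ratio < 0.8


class TestFeasibility:
    def test_infeasible_prophage_fails_before_writing(self, tmp_path):
        cfg = _tiny_config(contig_length_bp=4_000)   # prophage 5 kb > contig
        out = tmp_path / "bundle"
        with pytest.raises(ValueError, match="prophage"):
            generate(cfg, out)
        assert not out.exists()

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            PlantedMotif(Motif("GATC", 1, "6mA"), 1.3, 0.0)
        with pytest.raises(ValueError):
            SimulationConfig(diff_delta=1.5).validate()

    def test_type_iv_mtase_spec_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(rm_table_spec={"IV": (1, 0, 0)}).validate()


class TestBundleContents:
    def test_rm_table_orphan_truth(self, small_bundle):
        from metamethyl.rm_balance import orphan_mtases
        orphans = orphan_mtases(small_bundle.rm_genes)
        by_type = {}
        for g, _ in orphans:
            by_type[g.system_type] = by_type.get(g.system_type, 0) + 1
        assert by_type == {t: n for t, n in
                           small_bundle.truth["expected_orphans"].items()
                           if n > 0}

    def test_genes_do_not_overlap(self, small_bundle):
        by_contig = {}
        for g in small_bundle.genes:
            by_contig.setdefault(g.contig, []).append((g.start, g.end))
        for ivs in by_contig.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2

    def test_round_trip_through_files(self, bundle_dir, small_bundle):
        from metamethyl import io_formats
        contigs = io_formats.read_fasta(bundle_dir / "contigs.fasta")
        assert contigs == small_bundle.contigs
        sample = next(iter(small_bundle.sample_groups))
        df = io_formats.load_bedmethyl(
            bundle_dir / f"{sample}.bedmethyl", sample)
        sub = small_bundle.records[
            small_bundle.records["sample"] == sample]
        assert len(df) == len(sub)
        assert df["n_mod"].sum() == sub["n_mod"].sum()
        genes = io_formats.read_gff(bundle_dir / "genes.gff3")
        assert genes == small_bundle.genes
        rm = io_formats.read_rm_table(bundle_dir / "rm_genes.tsv")
        assert rm == small_bundle.rm_genes
        regions = io_formats.read_regions(bundle_dir / "regions.bed")
        assert regions == small_bundle.regions

    def test_config_yaml_round_trip(self, tmp_path):
        import yaml
        cfg = _tiny_config()
        path = tmp_path / "config.yaml"
        path.write_text(yaml.safe_dump(cfg.to_jsonable()))
        back = SimulationConfig.from_yaml(path)
        assert back == cfg


def test_simulate_instance_profiles_moments():
    rng = np.random.default_rng(8)
    profs = simulate_instance_profiles(n_instances=400, rng=rng)
    means = [p.group_mean["top"] for p in profs if p.has_data("top")]
    se = np.std(means, ddof=1) / np.sqrt(len(means))
    assert abs(np.mean(means) - 0.8) <= 3 * se
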