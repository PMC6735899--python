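"""Synthetic pool: spectrum, selection, read channel, determinism."""

import warnings

import numpy as np
import pytest

from poolscreen.align import KmerIndex, align_batch
from poolscreen.errors import ConfigError, DataError
from poolscreen.reference import OrfReference
from poolscreen.simulate import (
    MutagenesisConfig,
    MutantAllele,
    QualityModel,
    ReadSimConfig,
    apply_selection,
    mutagenize,
    simulate_reads,
    spiked_pool,
)


class TestMutagenize:
    def test_poisson_zero_mean_gives_reference_alleles(self, toy_ref):
        pool = mutagenize(toy_ref, MutagenesisConfig(0.0, 0.9, seed=1), 50)
        assert all(a.substitutions == () for a in pool)

    def test_forced_spectrum_is_all_gc_to_at(self, toy_ref):
        cfg = MutagenesisConfig(5.0, 1.0, seed=2)
        pool = mutagenize(toy_ref, cfg, 500)
        changes = [(r, a) for al in pool for (_, r, a) in al.substitutions]
        assert changes and all(c in (("C", "T"), ("G", "A")) for c in changes)

    def test_spectrum_within_binomial_band(self, toy_ref):
        """~10^4 induced changes at f=0.9 land within the 3-sigma band."""
        cfg = MutagenesisConfig(5.0, 0.9, seed=3)
        pool = mutagenize(toy_ref, cfg, 2000)
        changes = [(r, a) for al in pool for (_, r, a) in al.substitutions]
        n = len(changes)
        assert n > 8000
        frac = sum(c in (("C", "T"), ("G", "A")) for c in changes) / n
        assert abs(frac - 0.9) <= 3 * np.sqrt(0.9 * 0.1 / n)

    def test_substitutions_match_reference_and_are_unique(self, toy_ref):
        pool = mutagenize(toy_ref, MutagenesisConfig(3.0, 0.5, seed=4), 200)
        for allele in pool:
            allele.validate_against(toy_ref)  # raises on ref-base disagreement

    def test_no_gc_sites_with_bias_rejected(self):
        at_only = OrfReference(id="at", seq="ATAATTTAT")
        with pytest.raises(DataError, match="C/G"):
            mutagenize(at_only, MutagenesisConfig(1.0, 0.9, seed=5), 10)


class TestSelection:
    PHENO = {(4, "A"): "resistant_A", (10, "T"): "resistant_AB"}

    def _allele(self, ref, i, subs):
        return MutantAllele(
            allele_id=f"a{i}",
            substitutions=tuple((p, ref.base(p), alt) for p, alt in subs),
        )

    def test_all_labels_survive_is_identity(self, toy_ref):
        pool = [self._allele(toy_ref, i, [(4, "A")]) for i in range(5)]
        out = apply_selection(pool, self.PHENO, {"resistant_A", "resistant_AB", "sensitive"})
        assert len(out) == len(pool)

    def test_exact_filter_counts(self, toy_ref):
        resistant = [self._allele(toy_ref, i, [(4, "A")]) for i in range(50)]
        sensitive = [self._allele(toy_ref, 100 + i, []) for i in range(950)]
        out = apply_selection(resistant + sensitive, self.PHENO, {"resistant_A"})
        assert len(out) == 50
        assert all(a.truth_phenotype == "resistant_A" for a in out)

    def test_unlisted_allele_defaults_sensitive(self, toy_ref):
        pool = [self._allele(toy_ref, 0, [(7, "T") if toy_ref.base(7) != "T" else (7, "A")])]
        out = apply_selection(pool, self.PHENO, {"sensitive"})
        assert out[0].truth_phenotype == "sensitive"

    def test_empty_pool_warns(self, toy_ref):
        pool = [self._allele(toy_ref, 0, [])]
        with pytest.warns(UserWarning, match="empty pool"):
            out = apply_selection(pool, self.PHENO, {"resistant_A"})
        assert out == []

    def test_unknown_survival_label_rejected(self, toy_ref):
        with pytest.raises(ConfigError, match="unknown"):
            apply_selection([], self.PHENO, {"immortal"})


def _cfg(**kw):
    defaults = dict(
        n_reads=2000,
        read_length=100,
        fragment_min=200,
        fragment_max=500,
        quality_model=QualityModel.constant(40),
        error_coupling=False,
        seed=7,
    )
    defaults.update(kw)
    return ReadSimConfig(**defaults)


class TestSimulateReads:
    def test_byte_identical_under_same_seed(self, toy_ref, tmp_path):
        pool = mutagenize(toy_ref, MutagenesisConfig(1.5, 0.9, seed=1), 20)
        paths = [tmp_path / f"r{i}.fastq" for i in range(3)]
        truths = [tmp_path / f"t{i}.tsv" for i in range(3)]
        simulate_reads(toy_ref, pool, _cfg(error_coupling=True), paths[0], truths[0])
        simulate_reads(toy_ref, pool, _cfg(error_coupling=True), paths[1], truths[1])
        simulate_reads(toy_ref, pool, _cfg(error_coupling=True, seed=8), paths[2], truths[2])
        assert paths[0].read_bytes() == paths[1].read_bytes()
        assert truths[0].read_bytes() == truths[1].read_bytes()
        assert paths[0].read_bytes() != paths[2].read_bytes()

    def test_noise_free_reads_all_carry_the_spike(self, toy_ref, tmp_path):
        """Error channel off, single mutant allele: every read overlapping
        the site carries the alternate base, and the caller's support count
        equals the realized coverage exactly (end-to-end oracle)."""
        pos, alt = 451, ("A" if toy_ref.base(451) != "A" else "T")
        allele = MutantAllele("mut", ((pos, toy_ref.base(pos), alt),))
        fastq = tmp_path / "r.fastq"
        summary = simulate_reads(toy_ref, [allele], _cfg(), fastq)
        coverage = summary["per_mutation_coverage"][(pos, alt)]
        assert coverage > 0
        batch = align_batch(KmerIndex(toy_ref), fastq)
        obs = [o for o in batch["observations"] if (o.orf_pos, o.read_base) == (pos, alt)]
        assert len(obs) == coverage
        assert batch["mismatch_bearing_unique"] == coverage
        assert len(batch["observations"]) == coverage

    def test_error_rate_matches_phred_binomial(self):
        """Q=40 error coupling over 10^6 bases: realized miscall rate within
        3 sigma of 1e-4, measured independently against the known source."""
        # amplicon == fragment == read, so each read is the full amplicon
        # (either strand) and differences from it are exactly the errors
        ref = OrfReference(
            id="flat",
            seq="ATGGCACTATGCCGTATCGGACTTTGCACGATAGGCCATCGATTGACCAGT"
                "GGCATTACCGGATATTCAGCCATGATCTAAGGCATCGCA"[:90],
            flank5="GATTACCAGT",
        )
        assert len(ref.amplicon) == 100
        cfg = ReadSimConfig(
            n_reads=10_000, read_length=100, fragment_min=100, fragment_max=100,
            quality_model=QualityModel.constant(40), error_coupling=True, seed=11,
        )
        import tempfile
        from pathlib import Path
        from poolscreen.reference import reverse_complement

        with tempfile.TemporaryDirectory() as tmp:
            fq = Path(tmp) / "r.fastq"
            simulate_reads(ref, [MutantAllele("wt")], cfg, fq)
            lines = fq.read_text().splitlines()
        fwd, rev = ref.amplicon, reverse_complement(ref.amplicon)
        n_err = 0
        for i in range(1, len(lines), 4):
            read = lines[i]
            d_f = sum(a != b for a, b in zip(read, fwd))
            d_r = sum(a != b for a, b in zip(read, rev))
            n_err += min(d_f, d_r)
        n_bases = 10_000 * 100
        p = 1e-4
        assert abs(n_err - n_bases * p) <= 3 * np.sqrt(n_bases * p * (1 - p))

    def test_abundance_skew_drives_coverage_ratio(self, toy_ref, tmp_path):
        """Two alleles at 9:1 abundance: per-mutation coverage ratio lands
        within sampling error of 9:1 (multinomial oracle)."""
        p1, p2 = 450, 453
        a1 = ("A" if toy_ref.base(p1) != "A" else "T")
        a2 = ("A" if toy_ref.base(p2) != "A" else "T")
        pool = [
            MutantAllele("big", ((p1, toy_ref.base(p1), a1),), abundance=9.0),
            MutantAllele("small", ((p2, toy_ref.base(p2), a2),), abundance=1.0),
        ]
        summary = simulate_reads(toy_ref, pool, _cfg(n_reads=20_000, seed=13), tmp_path / "r.fastq")
        cov = summary["per_mutation_coverage"]
        ratio = cov[(p1, a1)] / cov[(p2, a2)]
        assert 7.3 <= ratio <= 11.0

    def test_truth_table_schema(self, toy_ref, tmp_path):
        pool = spiked_pool(toy_ref, [(4, "A"), (100, "T" if toy_ref.base(100) != "T" else "A")], 4, seed=3)
        truth = tmp_path / "truth.tsv"
        simulate_reads(toy_ref, pool, _cfg(n_reads=100), tmp_path / "r.fastq", truth)
        lines = truth.read_text().splitlines()
        assert lines[0].split("\t") == [
            "allele_id", "orf_pos", "ref_base", "alt_base",
            "ref_aa", "residue", "alt_aa", "abundance",
        ]
        assert len(lines) == 1 + 4  # one row per allele substitution

    def test_empty_pool_rejected(self, toy_ref, tmp_path):
        with pytest.raises(DataError, match="empty"):
            simulate_reads(toy_ref, [], _cfg(), tmp_path / "r.fastq")

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            ReadSimConfig(n_reads=0)
        with pytest.raises(ConfigError):
            ReadSimConfig(n_reads=10, fragment_min=500, fragment_max=200)
        with pytest.raises(ConfigError):
            ReadSimConfig(n_reads=10, read_length=300, fragment_min=200)
        with pytest.raises(ConfigError):
            MutagenesisConfig(gc_to_at_fraction=1.5)
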