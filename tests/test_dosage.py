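"""Window coverage, copy-number calls and parent-unique SNP contributions."""
import numpy as np
import pandas as pd
import pytest

from caninakit.dosage import (CoverageTrack, call_dosage, parent_unique_snps,
                              pileup_at_sites, snp_contribution,
                              window_coverage)
from caninakit.errors import CaninakitError
from caninakit.genome_map import ChromRecord, GenomeMap
from caninakit.meiosis import pentaploid_karyotype, predict_hybrid_dosage
from caninakit.simulate import (GenomeSpec, generate_pentaploid, generate_reads,
                                haplotype_collapse_map)


@pytest.fixture(scope="module")
def flat_map():
    return GenomeMap([
        ChromRecord("cS1", 1, "S1", "h1", 1_000_000),
        ChromRecord("cS2", 1, "S2", None, 1_000_000),
        ChromRecord("cR3", 1, "R3", None, 1_000_000),
        ChromRecord("cR4", 1, "R4", None, 1_000_000),
    ])


class TestWindowCoverage:
    def test_single_read_window_mean(self):
        aln = pd.DataFrame({"chrom": ["c1"], "start0": [100], "end": [250]})
        track = window_coverage(aln, {"c1": 10_000}, window_size=1_000)
        assert track.df.iloc[0]["depth"] == pytest.approx(150 / 1_000)
        assert track.df.iloc[1:]["depth"].sum() == 0

    def test_empty_alignments_all_zero(self):
        track = window_coverage(pd.DataFrame(columns=["chrom", "start0", "end"]),
                                {"c1": 5_000}, window_size=1_000)
        assert (track.df["depth"] == 0).all()
        assert len(track.df) == 5

    def test_last_window_short(self):
        track = window_coverage(pd.DataFrame(columns=["chrom", "start0", "end"]),
                                {"c1": 2_500}, window_size=1_000)
        assert track.df.iloc[-1]["end"] - track.df.iloc[-1]["start0"] == 500

    def test_unsorted_input_raises(self):
        aln = pd.DataFrame({"chrom": ["c1", "c1"], "start0": [500, 100],
                            "end": [600, 200]})
        with pytest.raises(CaninakitError, match="unsorted"):
            window_coverage(aln, {"c1": 10_000}, window_size=1_000)

    def test_conserves_total_mapped_bases(self, bundle_small):
        reads = generate_reads(bundle_small, source="genome", coverage=2,
                               seed=21, with_sequences=False)
        aln = reads.alignments()
        track = window_coverage(aln, bundle_small.chrom_lengths(),
                                window_size=10_000)
        win_bp = (track.df["depth"]
                  * (track.df["end"] - track.df["start0"])).sum()
        assert win_bp == pytest.approx(len(aln) * reads.read_length)

    def test_uniform_coverage_within_five_percent(self, bundle_small):
        reads = generate_reads(bundle_small, source="genome", coverage=30,
                               seed=22, with_sequences=False)
        track = window_coverage(reads.alignments(),
                                bundle_small.chrom_lengths(), window_size=10_000)
        assert track.df["depth"].mean() == pytest.approx(30, rel=0.05)


class TestCallDosage:
    def _track(self, depths, window=100_000):
        rows = []
        for chrom, d in depths.items():
            rows.append({"chrom": chrom, "start0": 0, "end": window, "depth": d})
            rows.append({"chrom": chrom, "start0": window, "end": 2 * window,
                         "depth": d})
        return CoverageTrack(pd.DataFrame(rows), window)

    def test_doubled_subgenome_pattern(self, flat_map):
        track = self._track({"cS1": 30, "cS2": 30, "cR3": 30, "cR4": 60})
        call = call_dosage(track, flat_map, baseline=["S2", "R3"])
        assert call.copy_number == {"S1": 1, "S2": 1, "R3": 1, "R4": 2}
        assert all(call.confident.values())

    def test_all_equal_depth_gives_all_ones(self, flat_map):
        track = self._track({"cS1": 25, "cS2": 25, "cR3": 25, "cR4": 25})
        call = call_dosage(track, flat_map, baseline=["S2", "R3"])
        assert set(call.copy_number.values()) == {1}

    def test_nonconfident_flag_between_integers(self, flat_map):
        track = self._track({"cS1": 45, "cS2": 30, "cR3": 30, "cR4": 30})
        call = call_dosage(track, flat_map, baseline=["S2", "R3"])
        assert not call.confident["S1"]

    def test_zero_baseline_raises(self, flat_map):
        track = self._track({"cS1": 30, "cS2": 0, "cR3": 0, "cR4": 30})
        with pytest.raises(CaninakitError, match="baseline"):
            call_dosage(track, flat_map, baseline=["S2", "R3"])

    def test_missing_baseline_subgenome_raises(self, flat_map):
        track = self._track({"cS1": 30})
        with pytest.raises(CaninakitError):
            call_dosage(track, flat_map, baseline=["S2"])

    @pytest.mark.parametrize("mother_biv, father_biv", [("S1", "R4"),
                                                        ("R4", "S1")])
    def test_generator_recovery_both_crosses(self, bundle_small,
                                             mother_biv, father_biv):
        mother = pentaploid_karyotype("m", mother_biv)
        father = pentaploid_karyotype("f", father_biv)
        expected = predict_hybrid_dosage(mother, father)
        reads = generate_reads(bundle_small, source=dict(expected), coverage=20,
                               seed=23, with_sequences=False)
        collapse = haplotype_collapse_map(bundle_small.genome_map)
        ref_lens = {c: L for c, L in bundle_small.chrom_lengths().items()
                    if not c.endswith("_h2")}
        track = window_coverage(reads.alignments(collapse=collapse), ref_lens,
                                window_size=10_000)
        repeat_ann = bundle_small.features[
            bundle_small.features["type"] == "repeat"]
        baseline = [s for s, n in expected.items() if n == 1]
        call = call_dosage(track, bundle_small.genome_map, baseline=baseline,
                           repeat_annotation=repeat_ann)
        assert call.copy_number == dict(expected)
        assert all(call.confident.values())


class TestParentUniqueSnps:
    def _vars(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos0", "ref", "alt"])

    def test_disjoint_sets_fully_retained(self):
        p1 = self._vars([("c1", 10, "A", "G"), ("c1", 20, "C", "T")])
        p2 = self._vars([("c1", 30, "G", "A")])
        out = parent_unique_snps(p1, p2, labels=("m", "f"))
        assert len(out) == 3
        assert set(out.df["parent"]) == {"m", "f"}

    def test_identical_sets_empty(self):
        p = self._vars([("c1", 10, "A", "G")])
        assert len(parent_unique_snps(p, p.copy())) == 0

    def test_symmetric_under_parent_swap(self):
        p1 = self._vars([("c1", 10, "A", "G"), ("c1", 20, "C", "T")])
        p2 = self._vars([("c1", 20, "C", "T"), ("c1", 40, "T", "A")])
        a = parent_unique_snps(p1, p2)
        b = parent_unique_snps(p2, p1)
        key = ["chrom", "pos0", "ref", "alt"]
        assert set(map(tuple, a.df[key].itertuples(index=False))) == \
            set(map(tuple, b.df[key].itertuples(index=False)))

    def test_conflicting_duplicates_warn_and_flag(self):
        p1 = self._vars([("c1", 10, "A", "G"), ("c1", 10, "A", "T")])
        p2 = self._vars([("c1", 99, "C", "T")])
        with pytest.warns(UserWarning, match="multi-allelic"):
            out = parent_unique_snps(p1, p2)
        flagged = out.df[out.df["pos0"] == 10]
        assert flagged["multiallelic"].all()


class TestSnpContribution:
    def test_clone_of_parent_one(self):
        snps = parent_unique_snps(
            pd.DataFrame([("c1", 10, "A", "G")],
                         columns=["chrom", "pos0", "ref", "alt"]),
            pd.DataFrame([("c1", 20, "C", "T")],
                         columns=["chrom", "pos0", "ref", "alt"]),
            labels=("p1", "p2"))
        pileup = pd.DataFrame([("c1", 10, "G", 8), ("c1", 20, "C", 9)],
                              columns=["chrom", "pos0", "base", "count"])
        rep = snp_contribution(pileup, snps, min_depth=1)
        assert rep.fractions["p1"] == 1.0
        assert rep.fractions["p2"] == 0.0

    def test_zero_depth_everywhere_raises(self):
        snps = parent_unique_snps(
            pd.DataFrame([("c1", 10, "A", "G")],
                         columns=["chrom", "pos0", "ref", "alt"]),
            pd.DataFrame([("c1", 20, "C", "T")],
                         columns=["chrom", "pos0", "ref", "alt"]))
        with pytest.raises(CaninakitError):
            snp_contribution(pd.DataFrame(columns=["chrom", "pos0", "base",
                                                   "count"]), snps)

    def test_empty_snpset_raises(self):
        from caninakit.dosage import SnpSet

        empty = SnpSet(pd.DataFrame(columns=["chrom", "pos0", "ref", "alt",
                                             "parent", "multiallelic"]))
        pileup = pd.DataFrame([("c1", 10, "G", 8)],
                              columns=["chrom", "pos0", "base", "count"])
        with pytest.raises(CaninakitError):
            snp_contribution(pileup, empty)


@pytest.fixture(scope="module")
def cross():
    common = dict(linkage_groups=2, chromosome_length=60_000,
                  centromere_length=8_000, n_sco_loci=2, ancestor_seed=900)
    mother = generate_pentaploid(GenomeSpec(seed=901, **common))
    father = generate_pentaploid(GenomeSpec(seed=902, **common))
    return mother, father


class TestGeneratorSnpContribution:
    """Two bundles on a shared ancestor frame act as the hybrid's parents."""

    def _parent_variants(self, bundle, ref_names):
        frames = []
        for rec in bundle.genome_map:
            ref = ref_names[rec.linkage_group]
            # planted substitutions, reported on the shared ancestor frame
            df = bundle.truth.substitution_frame(rec.name)
            df = df.assign(chrom=ref)
            frames.append(df)
        out = pd.concat(frames, ignore_index=True)
        return out.drop_duplicates(subset=["chrom", "pos0", "ref", "alt"])

    def test_father_fraction_matches_transmitted_subgenome(self, cross):
        mother, father = cross
        ref_names = {lg: f"anc{lg}" for lg in (1, 2)}
        mv = self._parent_variants(mother, ref_names)
        fv = self._parent_variants(father, ref_names)
        snps = parent_unique_snps(mv, fv, labels=("mother", "father"))

        collapse_m = {rec.name: ref_names[rec.linkage_group]
                      for rec in mother.genome_map}
        collapse_f = {rec.name: ref_names[rec.linkage_group]
                      for rec in father.genome_map}
        egg = generate_reads(mother, source={"S1": 1, "S2": 1, "R3": 1, "R4": 1},
                             coverage=15, error_rate=0.0, seed=31)
        sperm = generate_reads(father, source={"R4": 1}, coverage=15,
                               error_rate=0.0, seed=32)
        sites = snps.df[["chrom", "pos0"]].drop_duplicates()
        pile_m = pileup_at_sites(egg.truth, egg.seqs, sites,
                                 egg.read_length, collapse=collapse_m)
        pile_f = pileup_at_sites(sperm.truth, sperm.seqs, sites,
                                 sperm.read_length, collapse=collapse_f)
        pileup = (pd.concat([pile_m, pile_f])
                  .groupby(["chrom", "pos0", "base"], as_index=False)["count"]
                  .sum())
        rep = snp_contribution(pileup, snps, min_depth=3)

        assert rep.fractions["mother"] > 0.9
        father_unique = snps.for_parent("father")
        r4_sites = set()
        for rec in father.genome_map.chroms(subgenome="R4"):
            if rec.haplotype in (None, "h1"):
                pos, _, _ = father.truth.substitutions[rec.name]
                r4_sites |= {(ref_names[rec.linkage_group], int(p)) for p in pos}
        on_r4 = father_unique.apply(
            lambda r: (r["chrom"], r["pos0"]) in r4_sites, axis=1).mean()
        assert rep.fractions["father"] == pytest.approx(on_r4, abs=0.1)
        assert rep.fractions["father"] < rep.fractions["mother"]
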