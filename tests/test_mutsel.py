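"""Mutant-screen readout: subsampling, alignment, filtering, calling,
substitution profiles and differential enrichment."""

import numpy as np
import pandas as pd
import pytest

from t6kit import mutsel
from t6kit import synthdata as sd
from t6kit.io import FastqRead
from t6kit.synthdata.longreads import clone_sequence


def _read(seq, rid="r"):
    return FastqRead(rid, seq, [30] * len(seq))


@pytest.fixture(scope="module")
def locus(toy_locus_parts):
    cds, pmap = toy_locus_parts
    left, right = sd.random_flanks(30, seed=41)
    return mutsel.TargetLocus.from_cds(cds, pmap, left, right)


@pytest.fixture(scope="module")
def flanks():
    return sd.random_flanks(30, seed=41)


class TestSubsample:
    def test_identity_when_exact(self):
        reads = [_read("ACGT", f"r{i}") for i in range(5)]
        cfg = mutsel.MutselConfig(subsample_n=5)
        assert mutsel.subsample_reads(reads, cfg) == reads

    def test_deterministic_under_seed(self):
        reads = [_read("ACGT", f"r{i}") for i in range(10)]
        cfg = mutsel.MutselConfig(subsample_n=4, subsample_seed=3)
        assert mutsel.subsample_reads(reads, cfg) == \
            mutsel.subsample_reads(reads, cfg)

    def test_warns_when_short(self):
        reads = [_read("ACGT")]
        with pytest.warns(UserWarning, match="only 1 reads"):
            mutsel.subsample_reads(reads, mutsel.MutselConfig(subsample_n=5))

    def test_subsample_preserves_composition(self, toy_locus_parts):
        """Clone-of-origin proportions in an n=1000-of-10000 subsample match
        the source within 3 SE (hypergeometric)."""
        cds, pmap = toy_locus_parts
        clones, _ = sd.simulate_ep_library(
            sd.MutagenesisParams(cds, 1.0, 20, seed=42), pmap)
        ab = np.linspace(1, 2, 20)
        ab /= ab.sum()
        reads, truth = sd.simulate_long_reads(
            cds, clones, ab, sd.ReadErrorModel(seed=43), depth=10_000)
        clone_of = {t.read_id: t.clone_id for t in truth}
        cfg = mutsel.MutselConfig(subsample_n=1000, subsample_seed=44)
        subset = mutsel.subsample_reads(reads, cfg)
        top = clones[-1].clone_id
        p = np.mean([clone_of[r.read_id] == top for r in reads])
        p_hat = np.mean([clone_of[r.read_id] == top for r in subset])
        se = np.sqrt(p * (1 - p) / 1000 * (1 - 1000 / 10_000))
        assert abs(p_hat - p) <= 3 * se


class TestAlign:
    def test_error_free_full_length_read(self, locus):
        aln = mutsel.align_reads([_read(locus.reference)], locus)[0]
        assert aln.ref_start == 0 and aln.ref_end == len(locus)
        assert aln.left_clip == 0 and aln.right_clip == 0
        ref_codes = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b]
                              for b in locus.reference], dtype=np.uint8)
        assert (aln.calls == ref_codes).all()

    def test_single_injected_substitution_called_at_its_position(self, locus):
        pos = 100
        ref = locus.reference
        alt = "ACGT".replace(ref[pos], "")[0]
        read = _read(ref[:pos] + alt + ref[pos + 1:])
        aln = mutsel.align_reads([read], locus)[0]
        codes = "ACGT"
        mismatches = [i for i in range(aln.ref_start, aln.ref_end)
                      if aln.calls[i - aln.ref_start] < 4
                      and codes[aln.calls[i - aln.ref_start]] != ref[i]]
        assert mismatches == [pos]

    def test_unalignable_read_discarded(self, locus):
        junk = _read("AT" * (len(locus) // 2))
        assert mutsel.align_reads([junk], locus) == []

    def test_mean_mismatches_match_binomial_expectation(self, toy_locus_parts,
                                                        flanks):
        cds, pmap = toy_locus_parts
        left, right = flanks
        locus = mutsel.TargetLocus.from_cds(cds, pmap, left, right)
        clones, _ = sd.simulate_ep_library(
            sd.MutagenesisParams(cds, 0.0, 5, seed=45), pmap)
        ab = np.full(5, 0.2)
        rate = 0.02
        reads, _ = sd.simulate_long_reads(
            cds, clones, ab, sd.ReadErrorModel(sub_rate=rate, seed=46),
            depth=100, left_flank=left, right_flank=right)
        alns = mutsel.align_reads(reads, locus)
        L = len(locus)
        ref_codes = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b]
                              for b in locus.reference], dtype=np.uint8)
        mismatches = [
            int(((a.calls < 4)
                 & (a.calls != ref_codes[a.ref_start:a.ref_end])).sum())
            for a in alns]
        se = np.sqrt(L * rate * (1 - rate) / len(alns))
        assert abs(np.mean(mismatches) - rate * L) <= 3 * se


class TestFullLengthFilter:
    def _aln(self, start, end, left_clip=0, right_clip=0):
        return mutsel.AlignedRead("r", start, end,
                                  np.zeros(end - start, dtype=np.uint8),
                                  left_clip, right_clip)

    def test_spanning_read_kept(self, locus):
        a = self._aln(0, len(locus))
        assert mutsel.filter_full_length([a], locus) == [a]

    def test_late_start_excluded(self, locus):
        cfg = mutsel.MutselConfig(clip_tolerance=20)
        a = self._aln(50, len(locus))
        assert mutsel.filter_full_length([a], locus, cfg) == []

    def test_retained_fraction_tracks_truncation_probability(
            self, toy_locus_parts, flanks):
        cds, pmap = toy_locus_parts
        left, right = flanks
        locus = mutsel.TargetLocus.from_cds(cds, pmap, left, right)
        clones, _ = sd.simulate_ep_library(
            sd.MutagenesisParams(cds, 1.0, 50, seed=47), pmap)
        ab = np.full(50, 0.02)
        p, depth = 0.2, 2000
        reads, truth = sd.simulate_long_reads(
            cds, clones, ab, sd.ReadErrorModel(truncation_prob=p, seed=48),
            depth=depth, left_flank=left, right_flank=right)
        alns = mutsel.align_reads(reads, locus)
        kept = mutsel.filter_full_length(alns, locus)
        frac = len(kept) / depth
        se = np.sqrt(p * (1 - p) / depth)
        assert abs(frac - (1 - p)) <= 3 * se

    def test_filter_agrees_exactly_with_simulator_truth(self, toy_locus_parts,
                                                        flanks):
        """The full-length filter retains exactly the non-truncated reads
        (min_truncation far exceeds the clip tolerance)."""
        cds, pmap = toy_locus_parts
        left, right = flanks
        locus = mutsel.TargetLocus.from_cds(cds, pmap, left, right)
        clones, _ = sd.simulate_ep_library(
            sd.MutagenesisParams(cds, 1.0, 50, seed=49), pmap)
        ab = np.full(50, 0.02)
        reads, truth = sd.simulate_long_reads(
            cds, clones, ab,
            sd.ReadErrorModel(truncation_prob=0.3, min_truncation=60, seed=50),
            depth=1000, left_flank=left, right_flank=right)
        alns = mutsel.align_reads(reads, locus)
        kept = {a.read_id for a in mutsel.filter_full_length(alns, locus)}
        expected = {t.read_id for t in truth if not t.truncated}
        assert kept == expected

    def test_filter_never_increases_reads(self, locus):
        alns = [self._aln(0, len(locus)), self._aln(100, len(locus))]
        assert len(mutsel.filter_full_length(alns, locus)) <= len(alns)


class TestCallVariants:
    def test_reference_reads_give_no_calls(self, locus):
        alns = mutsel.align_reads([_read(locus.reference, f"r{i}")
                                   for i in range(4)], locus)
        cfg = mutsel.MutselConfig(min_variant_reads=1)
        assert mutsel.call_variants(alns, locus, cfg).empty

    def test_frequency_counts_covering_reads(self, locus):
        """4 of 10 covering reads carry an alternate base -> frequency 0.4."""
        ref = locus.reference
        pos = 67
        alt = "ACGT".replace(ref[pos], "")[0]
        reads = [_read(ref, f"ref{i}") for i in range(6)]
        reads += [_read(ref[:pos] + alt + ref[pos + 1:], f"alt{i}")
                  for i in range(4)]
        alns = mutsel.align_reads(reads, locus)
        calls = mutsel.call_variants(alns, locus,
                                     mutsel.MutselConfig(min_variant_reads=1))
        row = calls[calls["position"] == pos].iloc[0]
        assert row["n_alt"] == 4 and row["coverage"] == 10
        assert row["frequency"] == pytest.approx(0.4)

    def test_uncovered_site_yields_no_call_not_zero(self, locus):
        """Reads covering only the left half produce no call (rather than
        frequency 0) at right-half positions."""
        half = _read(locus.reference[: len(locus) // 2])
        alns = mutsel.align_reads([half], locus)
        calls = mutsel.call_variants(alns, locus,
                                     mutsel.MutselConfig(min_variant_reads=1))
        assert (calls["position"] < len(locus) // 2 + 5).all()

    def test_noise_floor_suppresses_error_frequency_alleles(self, locus):
        ref = locus.reference
        pos = 90
        alt = "ACGT".replace(ref[pos], "")[0]
        reads = [_read(ref, f"ref{i}") for i in range(97)]
        reads += [_read(ref[:pos] + alt + ref[pos + 1:], f"alt{i}")
                  for i in range(3)]
        alns = mutsel.align_reads(reads, locus)
        cfg = mutsel.MutselConfig(min_variant_reads=1, error_rate=0.05)
        calls = mutsel.call_variants(alns, locus, cfg)
        assert calls[calls["position"] == pos].empty  # 3% < 3 x 5% floor


class TestSubstitutionProfiles:
    def test_synonymous_variants_do_not_contribute(self, toy_locus_parts):
        cds, pmap = toy_locus_parts
        locus = mutsel.TargetLocus(cds, pmap)
        # find a synonymous single-nt change in the first codon family
        from t6kit.synthdata.epcr import classify_variant

        found = None
        for pos in range(len(cds)):
            for alt in "ACGT":
                if alt == cds[pos]:
                    continue
                ch = classify_variant(cds, pmap, pos, alt)
                if ch.consequence == "synonymous":
                    found = (pos, alt)
                    break
            if found:
                break
        pos, alt = found
        reads = [_read(cds, f"ref{i}") for i in range(5)]
        reads += [_read(cds[:pos] + alt + cds[pos + 1:], f"syn{i}")
                  for i in range(5)]
        alns = mutsel.align_reads(reads, locus)
        cfg = mutsel.MutselConfig(min_variant_reads=1)
        prof = mutsel.aa_substitution_frequencies(
            mutsel.call_variants(alns, locus, cfg), locus, cfg)
        assert prof.empty

    def test_missense_frequency_counted_per_residue(self, toy_locus_parts):
        """4 of 10 reads carrying a missense codon change give f = 0.4 at
        that residue, in both calling modes."""
        cds, pmap = toy_locus_parts
        locus = mutsel.TargetLocus(cds, pmap)
        pid, start, _ = pmap[1]
        residue = 7
        codon_start = start + 3 * (residue - 1)
        ref_codon = cds[codon_start:codon_start + 3]
        from t6kit.synthdata.epcr import classify_variant
        pos = alt = None
        for off in range(3):
            for cand in "ACGT":
                if cand == ref_codon[off]:
                    continue
                ch = classify_variant(cds, pmap, codon_start + off, cand)
                if ch.consequence == "missense":
                    pos, alt, alt_aa = codon_start + off, cand, ch.alt_aa
                    break
            if pos is not None:
                break
        reads = [_read(cds, f"ref{i}") for i in range(6)]
        reads += [_read(cds[:pos] + alt + cds[pos + 1:], f"mis{i}")
                  for i in range(4)]
        alns = mutsel.align_reads(reads, locus)
        for mode in ("variant_level", "codon_level"):
            cfg = mutsel.MutselConfig(min_variant_reads=1, calling_mode=mode)
            source = mutsel.call_variants(alns, locus, cfg) \
                if mode == "variant_level" else alns
            prof = mutsel.aa_substitution_frequencies(source, locus, cfg)
            row = prof[(prof["protein_id"] == pid)
                       & (prof["residue_index"] == residue)]
            assert row["frequency"].iloc[0] == pytest.approx(0.4)
            assert row["alt_aa"].iloc[0] == alt_aa

    @pytest.mark.parametrize("mode", ["variant_level", "codon_level"])
    def test_exhaustive_error_free_reads_recover_truth_exactly(
            self, toy_locus_parts, mode):
        """One error-free read per clone: profiles equal the simulator truth
        to 1e-12 (the end-to-end oracle)."""
        cds, pmap = toy_locus_parts
        left, right = sd.random_flanks(30, seed=41)
        locus = mutsel.TargetLocus.from_cds(cds, pmap, left, right)
        n = 256  # power of two so clone fractions are exact dyadics
        clones, truth = sd.simulate_ep_library(
            sd.MutagenesisParams(cds, 3.0, n, seed=51), pmap)
        reads = [_read(left + clone_sequence(cds, c) + right, c.clone_id)
                 for c in clones]
        cfg = mutsel.MutselConfig(subsample_n=n, min_variant_reads=1,
                                  calling_mode=mode)
        alns = mutsel.filter_full_length(
            mutsel.align_reads(reads, locus, cfg), locus, cfg)
        assert len(alns) == n
        source = mutsel.call_variants(alns, locus, cfg) \
            if mode == "variant_level" else alns
        prof = mutsel.profile_per_residue(
            mutsel.aa_substitution_frequencies(source, locus, cfg))
        expected = truth.expected_profile(np.full(n, 1.0 / n), mode=mode)
        assert set(prof.index) == set(expected.index)
        diffs = (prof - expected).abs()
        assert diffs.max() < 1e-12

    def test_profiles_invariant_to_read_order_and_duplication(
            self, toy_locus_parts):
        cds, pmap = toy_locus_parts
        locus = mutsel.TargetLocus(cds, pmap)
        clones, _ = sd.simulate_ep_library(
            sd.MutagenesisParams(cds, 3.0, 64, seed=52), pmap)
        reads = [_read(clone_sequence(cds, c), c.clone_id) for c in clones]
        cfg = mutsel.MutselConfig(subsample_n=10_000, min_variant_reads=1)

        def profile(rds):
            alns = mutsel.align_reads(rds, locus, cfg)
            return mutsel.profile_per_residue(mutsel.aa_substitution_frequencies(
                mutsel.call_variants(alns, locus, cfg), locus, cfg))

        base = profile(reads)
        pd.testing.assert_series_equal(base, profile(reads[::-1]))
        pd.testing.assert_series_equal(base, profile(reads + reads))


class TestDifferentialEnrichment:
    def _profile(self, entries):
        return pd.DataFrame(entries, columns=["protein_id", "residue_index",
                                              "alt_aa", "frequency"])

    def test_identical_profiles_give_unit_enrichment(self):
        p = self._profile([("rnfG", 5, "E", 0.1), ("rnfD", 2, "K", 0.05)])
        cfg = mutsel.MutselConfig(subsample_n=1000)
        table = mutsel.differential_enrichment(p, [p, p], cfg)
        assert (table["E"] == 1.0).all()
        assert not table["selected_only"].any()

    def test_fifteen_fold_arithmetic(self):
        sel = self._profile([("rnfG", 27, "D", 0.0015)])
        ctrl = self._profile([("rnfG", 27, "D", 0.0001)])
        cfg = mutsel.MutselConfig(subsample_n=100_000)
        table = mutsel.differential_enrichment(sel, [ctrl], cfg)
        assert table["E"].iloc[0] == pytest.approx(15.0)

    def test_selected_only_flag_and_epsilon_floor(self):
        sel = self._profile([("rnfG", 23, "E", 0.02)])
        ctrl = self._profile([])
        cfg = mutsel.MutselConfig(subsample_n=1000)
        table = mutsel.differential_enrichment(sel, [ctrl], cfg)
        row = table.loc[("rnfG", 23)]
        assert row["selected_only"]
        assert row["E"] == pytest.approx(0.02 / (1 / 1000))

    def test_empty_controls_rejected(self):
        sel = self._profile([("rnfG", 23, "E", 0.02)])
        with pytest.raises(ValueError, match="control"):
            mutsel.differential_enrichment(sel, [])


def test_more_sequencing_error_never_reduces_raw_variant_calls(
        toy_locus_parts, flanks):
    cds, pmap = toy_locus_parts
    left, right = flanks
    locus = mutsel.TargetLocus.from_cds(cds, pmap, left, right)
    clones, _ = sd.simulate_ep_library(
        sd.MutagenesisParams(cds, 1.0, 30, seed=53), pmap)
    ab = np.full(30, 1 / 30)
    cfg = mutsel.MutselConfig(min_variant_reads=1)
    n_calls = []
    for rate in (0.0, 0.01, 0.05):
        reads, _ = sd.simulate_long_reads(
            cds, clones, ab, sd.ReadErrorModel(sub_rate=rate, seed=54),
            depth=300, left_flank=left, right_flank=right)
        alns = mutsel.align_reads(reads, locus, cfg)
        n_calls.append(len(mutsel.call_variants(alns, locus, cfg)))
    assert n_calls == sorted(n_calls)
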