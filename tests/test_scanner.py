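import math

import numpy as np
import pytest

from cbscan import composition, fixtures, scanner, seqio
from cbscan.binom import tail_row
from cbscan.scanner import BiasedRegion, ScanParams, annotate, merge, minimize, quick_scan, trim
from cbscan.seqio import DNA, PROTEIN, SequenceRecord
from conftest import make_protein_comp
from helpers_oracle import brute_best_interval, reverse_complement


def prot(seq, seq_id="s"):
    return SequenceRecord(seq_id, "", seq, PROTEIN)


class TestScanParams:
    def test_mode_table(self):
        p = ScanParams(PROTEIN, precision="medium")
        assert p.baseline_p0 == 0.01 and p.step == 2
        p = ScanParams(PROTEIN, precision="thorough")
        assert p.baseline_p0 == 0.1 and p.step == 1
        p = ScanParams(PROTEIN)
        assert p.baseline_p0 == 0.001 and p.step == 3

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            ScanParams(PROTEIN, m=30, M=20)

    def test_positive_t_rejected(self):
        with pytest.raises(ValueError):
            ScanParams(PROTEIN, t=0.5)

    def test_restriction_outside_alphabet_rejected(self):
        with pytest.raises(ValueError):
            ScanParams(DNA, restriction=frozenset("FYW"))


class TestQuickScan:
    def test_single_all_biased_window(self, uniform_protein_comp):
        rec = prot("E" * 15)
        out = quick_scan(rec, uniform_protein_comp, ScanParams(PROTEIN))
        assert set(out) == {"E"}
        (contig,) = out["E"]
        assert (contig.start, contig.end) == (1, 15)
        assert contig.member_windows == 1

    def test_restriction_filters_residues(self, uniform_protein_comp):
        rec = prot("E" * 15)
        params = ScanParams(PROTEIN, restriction=frozenset("K"))
        assert quick_scan(rec, uniform_protein_comp, params) == {}

    def test_short_sequence_is_empty_not_error(self, uniform_protein_comp):
        rec = prot("EEEE")
        assert quick_scan(rec, uniform_protein_comp, ScanParams(PROTEIN)) == {}

    def test_terminal_window_always_anchored(self, uniform_protein_comp):
        # biased tract flush with the end, at an offset unreachable by step=3
        rec = prot("L" * 17 + "E" * 15)
        out = quick_scan(rec, uniform_protein_comp, ScanParams(PROTEIN))
        (contig,) = out["E"]
        assert contig.end == 32

    def test_kept_window_fraction_calibrated(self, uniform_dna_comp):
        """Monte-Carlo false-positive calibration on uniform DNA.

        The expected kept fraction per residue equals the tail probability at
        the smallest count beating the baseline.  Windows overlap (m=15,
        step=3), so the 3-sigma band uses the disjoint-window count.
        """
        params = ScanParams(DNA)
        m = params.m
        row = tail_row(m, 0.25)
        k_star = int(np.argmax(row < math.log10(params.baseline_p0)))
        expect = 10 ** row[k_star]
        kept = total = 0
        for seed in range(50):
            rec, _ = fixtures.generate(10_000, uniform_dna_comp, seed=seed)
            out = quick_scan(rec, uniform_dna_comp, params)
            contigs = out.get("A", [])
            kept += sum(c.member_windows for c in contigs)
            total += len(scanner._window_starts(10_000, m, params.step))
        obs = kept / total
        n_eff = total * params.step / m
        sigma = math.sqrt(expect * (1 - expect) / n_eff)
        assert abs(obs - expect) < 3 * sigma


class TestMinimize:
    def test_pure_tract_is_its_own_minimizer(self, protein_comp_factory):
        comp = protein_comp_factory({"E": 0.068})
        rec = prot("E" * 20)
        params = ScanParams(PROTEIN)
        (contig,) = quick_scan(rec, comp, params)["E"]
        reg = minimize(rec, contig, comp, params)
        assert (reg.start, reg.end) == (1, 20)
        assert reg.logp == pytest.approx(20 * math.log10(0.068), abs=1e-9)

    def test_right_boundary_excludes_unbiased_tail(self, protein_comp_factory):
        comp = protein_comp_factory({"K": 0.05})
        rec = prot("K" * 10 + "A" * 10)
        params = ScanParams(PROTEIN, m=5)
        (contig,) = quick_scan(rec, comp, params)["K"]
        reg = minimize(rec, contig, comp, params)
        assert reg.end == 10
        assert reg.start == 1

    def test_below_threshold_returns_none(self, uniform_protein_comp):
        rec = prot("E" * 15 + "A" * 10)
        params = ScanParams(PROTEIN, t=math.log10(1e-30))
        (contig,) = quick_scan(rec, uniform_protein_comp, params)["E"]
        assert minimize(rec, contig, uniform_protein_comp, params) is None

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_exhaustive_subinterval_search(self, seed, uniform_protein_comp):
        """Brute-force equivalence on short implanted sequences (thorough)."""
        comp = uniform_protein_comp
        rec, truth = fixtures.generate(
            260,
            comp,
            [fixtures.ImplantSpec(90, 30, "N", 0.85)],
            seed=seed,
            seq_id=f"bf{seed}",
        )
        params = ScanParams(PROTEIN, precision="thorough")
        regions = [
            g for g in annotate(rec, comp, params) if g.residue_set == ("N",)
        ]
        assert regions, "implant must be recovered"
        best = min(regions, key=lambda g: g.logp)
        want = brute_best_interval(rec.residues, "N", comp.freq["N"], 15, 500)
        assert best.logp == pytest.approx(want[0], abs=1e-9)
        assert (best.start, best.end) == (want[1], want[2])


class TestTrim:
    def _region(self, rec, start, end, residue, params, comp):
        piece = rec.residues[start - 1 : end]
        k = piece.count(residue)
        lp = float(tail_row(end - start + 1, comp.freq[residue])[k])
        return BiasedRegion(rec.id, start, end, (residue,), {residue: k}, lp, "single")

    def test_shears_both_ends(self, protein_comp_factory):
        comp = protein_comp_factory({"E": 0.05})
        rec = prot("AEEEEEEEEEEEEEA")
        params = ScanParams(PROTEIN)
        reg = self._region(rec, 1, 15, "E", params, comp)
        trimmed = trim(reg, rec, comp, params)
        assert (trimmed.start, trimmed.end) == (2, 14)
        assert trimmed.counts == {"E": 13}
        assert trimmed.logp == pytest.approx(13 * math.log10(0.05), abs=1e-9)
        assert trimmed.logp <= reg.logp

    def test_fixed_point_when_ends_biased(self, protein_comp_factory):
        comp = protein_comp_factory({"E": 0.05})
        rec = prot("E" + "A" * 6 + "E" * 7 + "E")
        params = ScanParams(PROTEIN)
        reg = self._region(rec, 1, 15, "E", params, comp)
        assert trim(reg, rec, comp, params) is reg

    def test_trimmed_fraction_band_on_synthetic_proteome(self, uniform_protein_comp):
        """Trimming alters a small percentage of all regions (loose band).

        Only minimum-length regions can change; over a corpus with varied
        implant lengths and concentrations the altered share of all regions
        sits in the mid single digits, checked here as a loose band rather
        than a gate.
        """
        comp = uniform_protein_comp
        params = ScanParams(PROTEIN, t=math.log10(1e-4))
        residues = "SQNEKGPT"
        n_all = n_trimmed = 0
        for seed in range(150):
            length = 15 + (seed * 7) % 45
            conc = 0.7 + 0.3 * ((seed * 13) % 10) / 9
            rec, _ = fixtures.generate(
                400,
                comp,
                [
                    fixtures.ImplantSpec(
                        150, length, residues[seed % len(residues)], conc,
                        seed=seed + 1,
                    )
                ],
                seed=seed,
            )
            contigs = quick_scan(rec, comp, params)
            for r, cs in contigs.items():
                for contig in cs:
                    best = scanner._best_subinterval(
                        rec, contig.start, contig.end, r, comp.freq[r], params, params.M
                    )
                    if best is None or best[0] > params.t:
                        continue
                    lo, hi = best[1], best[2]
                    n_all += 1
                    if hi - lo + 1 != params.m:
                        continue
                    piece = rec.residues[lo - 1 : hi]
                    if piece[0] != r or piece[-1] != r:
                        n_trimmed += 1
        assert n_all > 100
        frac = n_trimmed / n_all
        assert 0.005 < frac < 0.15


class TestMerge:
    def test_non_overlapping_regions_do_not_merge(self, protein_comp_factory):
        comp = protein_comp_factory({"E": 0.05, "K": 0.05})
        rec = prot("E" * 20 + "L" * 30 + "K" * 20)
        params = ScanParams(PROTEIN)
        regions = annotate(rec, comp, params)
        assert all(g.kind == "single" for g in regions)

    def test_joint_tail_from_pooled_counts(self, protein_comp_factory):
        comp = protein_comp_factory({"D": 0.055, "E": 0.055})
        rec = prot("DEDEDEDEDEDEDEDE")
        params = ScanParams(PROTEIN)
        regions = annotate(rec, comp, params)
        multi = [g for g in regions if g.kind == "multiple"]
        assert len(multi) == 1
        joint = multi[0]
        assert set(joint.residue_set) == {"D", "E"}
        assert (joint.start, joint.end) == (1, 16)
        assert joint.logp == pytest.approx(16 * math.log10(0.11), abs=1e-9)
        singles = [g for g in regions if g.kind == "single"]
        assert joint.logp < min(g.logp for g in singles)

    def test_coextensive_biases_merge_to_strongest_extent(self, protein_comp_factory):
        comp = protein_comp_factory({"P": 0.05, "Y": 0.03, "Q": 0.04})
        core = "P" + "YQP" * 11 + "P"
        rec = prot("A" * 8 + core + "A" * 8)
        params = ScanParams(PROTEIN)
        regions = annotate(rec, comp, params)
        p_reg = next(g for g in regions if g.residue_set == ("P",))
        multi = [g for g in regions if g.kind == "multiple"]
        assert len(multi) == 1
        joint = multi[0]
        assert set(joint.residue_set) == {"P", "Y", "Q"}
        assert (joint.start, joint.end) == (p_reg.start, p_reg.end)
        assert joint.logp < p_reg.logp
        # precedence order: ascending single-residue tail, recomputed here
        by_tail = sorted(
            (
                g
                for g in regions
                if g.kind == "single" and set(g.residue_set) <= {"P", "Y", "Q"}
            ),
            key=lambda g: (g.logp, g.residue_set[0]),
        )
        assert joint.residue_set == tuple(g.residue_set[0] for g in by_tail)
        assert joint.signature == "{" + "".join(joint.residue_set) + "}"

    def test_merged_region_may_exceed_max_window(self, protein_comp_factory):
        comp = protein_comp_factory({"D": 0.05, "E": 0.05})
        rec = prot("D" * 12 + "DE" * 6 + "E" * 12)
        params = ScanParams(PROTEIN, M=20)
        regions = annotate(rec, comp, params)
        multi = [g for g in regions if g.kind == "multiple"]
        assert multi and max(g.length for g in multi) > params.M


class TestAnnotate:
    def test_uniform_random_is_empty_at_tight_threshold(self, uniform_protein_comp):
        params = ScanParams(PROTEIN, t=math.log10(1e-9))
        for seed in range(25):
            rec, _ = fixtures.generate(500, uniform_protein_comp, seed=seed)
            assert annotate(rec, uniform_protein_comp, params) == []

    def test_single_implant_recovered(self, uniform_protein_comp):
        rec, truth = fixtures.generate(
            400,
            uniform_protein_comp,
            [fixtures.ImplantSpec(180, 30, "Q", 1.0)],
            seed=3,
        )
        params = ScanParams(PROTEIN, t=math.log10(1e-5))
        regions = [
            g
            for g in annotate(rec, uniform_protein_comp, params)
            if g.residue_set == ("Q",)
        ]
        assert len(regions) == 1
        (s, e, _) = truth[0]
        ov = min(e, regions[0].end) - max(s, regions[0].start) + 1
        assert ov >= 0.9 * (e - s + 1)

    def test_thorough_finds_at_least_as_many_as_fast(self, uniform_protein_comp):
        # well-separated single-residue implants: the direction holds cleanly
        # (coalescing contigs can merge two weak regions into one, see ledger)
        for seed in range(8):
            rec, _ = fixtures.generate(
                500,
                uniform_protein_comp,
                [
                    fixtures.ImplantSpec(100, 30, "S", 0.8, seed=seed),
                    fixtures.ImplantSpec(350, 30, "T", 0.8, seed=seed + 100),
                ],
                seed=seed,
            )
            counts = {}
            for mode in ("fast", "thorough"):
                params = ScanParams(PROTEIN, precision=mode)
                counts[mode] = len(annotate(rec, uniform_protein_comp, params))
            assert counts["thorough"] >= counts["fast"]

    def test_restriction_soundness(self, uniform_protein_comp):
        rec, _ = fixtures.generate(
            400,
            uniform_protein_comp,
            [
                fixtures.ImplantSpec(50, 30, "E", 0.9),
                fixtures.ImplantSpec(200, 30, "K", 0.9),
            ],
            seed=5,
        )
        params = ScanParams(PROTEIN, restriction=frozenset("E"))
        regions = annotate(rec, uniform_protein_comp, params)
        assert regions
        assert all(set(g.residue_set) <= {"E"} for g in regions)

    def test_region_invariants(self, uniform_protein_comp):
        params = ScanParams(PROTEIN)
        for seed in range(5):
            rec, _ = fixtures.generate(
                600,
                uniform_protein_comp,
                [fixtures.ImplantSpec(100, 35, "G", 0.9), fixtures.ImplantSpec(300, 35, "GN", 0.9)],
                seed=seed,
            )
            for g in annotate(rec, uniform_protein_comp, params):
                assert g.logp <= params.t
                assert 1 <= g.start <= g.end <= len(rec)
                piece = rec.residues[g.start - 1 : g.end]
                for r in g.residue_set:
                    assert piece.count(r) == g.counts[r]
                assert piece[0] in g.residue_set and piece[-1] in g.residue_set
                assert g.enrichment > 1.0

    def test_dna_strand_symmetry(self, uniform_dna_comp):
        params = ScanParams(DNA, precision="thorough")
        rec, _ = fixtures.generate(
            800,
            uniform_dna_comp,
            [
                fixtures.ImplantSpec(100, 40, "A", 0.85),
                fixtures.ImplantSpec(400, 50, "GT", 0.8),
            ],
            seed=11,
        )
        fwd = annotate(rec, uniform_dna_comp, params)
        rc = SequenceRecord("rc", "", reverse_complement(rec.residues), DNA)
        rev = annotate(rc, uniform_dna_comp, params)
        assert len(fwd) == len(rev)
        L = len(rec)
        comp_map = str.maketrans("ACGT", "TGCA")
        fwd_set = {
            (g.start, g.end, frozenset(g.residue_set), round(g.logp, 6))
            for g in fwd
        }
        rev_set = {
            (
                L - g.end + 1,
                L - g.start + 1,
                frozenset("".join(g.residue_set).translate(comp_map)),
                round(g.logp, 6),
            )
            for g in rev
        }
        assert fwd_set == rev_set


class TestUnknownHandling:
    def test_unknowns_never_bias(self, uniform_protein_comp):
        rec = prot("X" * 40)
        params = ScanParams(PROTEIN)
        assert annotate(rec, uniform_protein_comp, params) == []

    def test_ignore_unknown_strengthens_bias(self, protein_comp_factory):
        comp = protein_comp_factory({"E": 0.05})
        seq = "EEEEEXEEEEEXEEEEE"
        rec = prot(seq)
        base = ScanParams(PROTEIN, m=10)
        keep = annotate(rec, comp, base)
        skip = annotate(rec, comp, ScanParams(PROTEIN, m=10, ignore_unknown=True))
        e_keep = min(g.logp for g in keep if g.residue_set == ("E",))
        e_skip = min(g.logp for g in skip if g.residue_set == ("E",))
        # same 15 E's, but the window length shrinks by the 2 X's
        assert e_skip < e_keep
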