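"""RCL annotation: hinge scanning, P1 prediction, classification,
physicochemical features, family summaries, and isoform assembly."""

import numpy as np
import pytest

from serpinscape.rcl import (
    DEFAULT_WINDOW,
    HINGE_ALLOWED,
    annotate_rcl,
    assemble_isoforms,
    classify_specificity,
    compute_mw,
    compute_pi,
    scan_hinge,
    score_anchor,
    summarize_family,
)
from serpinscape.records import Exon, GeneModel, ProteinRecord
from serpinscape.simulate import gen_serpin_proteins

from conftest import random_protein


def brute_force_scan(seq, window=DEFAULT_WINDOW):
    """Independent exhaustive enumeration of every anchor in the window."""
    L = len(seq)
    lo = max(1, L - window.max_from_cterm)
    hi = min(L - window.min_from_cterm, L - 8)
    out = []
    for p17 in range(lo, hi + 1):
        hits = [seq[p17 - 1 + off] in allowed for off, allowed in HINGE_ALLOWED]
        if sum(hits) >= 1:
            out.append((sum(hits), p17))
    out.sort(key=lambda t: (-t[0], -t[1]))
    return out


class TestScanHinge:
    def test_perfect_hinge_scores_eight(self, rng):
        seq = list(random_protein(rng, 400))
        p17 = 400 - 43  # segment ends 35 residues from the C-terminus
        seq[p17 - 1:p17 + 8] = list("EEGTEAAAA")
        matches = scan_hinge("".join(seq))
        assert matches[0].score == 8
        assert matches[0].p17_index == p17

    def test_homopolymer_has_no_matches(self):
        assert scan_hinge("P" * 100) == []

    def test_too_short_sequence_raises(self):
        with pytest.raises(ValueError, match="too short"):
            scan_hinge("A" * 39)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_protein(rng, 400)
        mine = [(m.score, m.p17_index) for m in scan_hinge(seq)]
        assert mine == brute_force_scan(seq)

    def test_score_equals_hit_count(self, rng):
        seq = random_protein(rng, 200)
        for p17 in range(130, 170):
            m = score_anchor(seq, p17)
            assert m.score == sum(m.per_position_hits)


class TestAnnotate:
    def _planted(self, rng, p1_res="R", d_from_cterm=50, length=400):
        seq = list(random_protein(rng, length))
        p17 = length - d_from_cterm
        seq[p17 - 1:p17 + 8] = list("EEGTXAAAA".replace("X", "L"))
        if p17 + 15 < length:
            seq[p17 + 15] = p1_res
        return ProteinRecord(id="x", sequence="".join(seq)), p17

    def test_perfect_hinge_is_inhibitory_with_p1_arithmetic(self, rng):
        rec, p17 = self._planted(rng)
        a = annotate_rcl(rec)
        assert a.inhibitory
        assert a.p1_index == p17 + 16
        assert a.p1p_index == a.p1_index + 1
        assert a.p1_residue == "R"
        assert a.specificity == "trypsin"

    def test_degraded_hinge_is_noninhibitory(self, rng):
        # mimics the weak-hinge paralogs: only 3/8 consensus positions
        seq = list(random_protein(rng, 380))
        p17 = 380 - 50
        seq[p17 - 1:p17 + 8] = list("EPGPPPPPA")  # hits: P17, P15, P9-ish
        rec = ProteinRecord(id="weak", sequence="".join(seq))
        a = annotate_rcl(rec)
        assert a.hinge is None or a.hinge.score < 6
        assert not a.inhibitory
        assert a.specificity == "none"

    def test_hinge_against_cterm_is_noninhibitory(self, rng):
        # RCL-less: hinge jammed so close to the end that no P1 remains in
        # the serpin-typical register
        rec, _ = self._planted(rng, d_from_cterm=12)
        a = annotate_rcl(rec)
        assert not a.inhibitory

    def test_unclassifiable_p1_is_noninhibitory(self, rng):
        rec, _ = self._planted(rng, p1_res="D")
        a = annotate_rcl(rec)
        assert not a.inhibitory and a.specificity == "none"


class TestSpecificity:
    @pytest.mark.parametrize("res,cls", [
        ("K", "trypsin"), ("R", "trypsin"),
        ("Y", "chymotrypsin"), ("L", "chymotrypsin"), ("I", "chymotrypsin"),
        ("F", "chymotrypsin"), ("W", "chymotrypsin"),
        ("M", "elastase"), ("A", "elastase"), ("V", "elastase"),
        ("G", "elastase"), ("S", "elastase"),
        ("D", "none"), ("H", "none"), ("P", "none"),
    ])
    def test_residue_class_map(self, res, cls):
        assert classify_specificity(res) == cls

    def test_invalid_residue_raises(self):
        with pytest.raises(ValueError):
            classify_specificity("Z")
        with pytest.raises(ValueError):
            classify_specificity("RK")


class TestPhysicochemical:
    def test_glycine_mass(self):
        assert compute_mw("G") * 1000 == pytest.approx(75.0672, abs=1e-3)

    def test_diglycine_mass(self):
        assert compute_mw("GG") * 1000 == pytest.approx(132.12, abs=0.01)

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            compute_mw("")

    def test_mass_additivity(self, rng):
        s1 = random_protein(rng, 40)
        s2 = random_protein(rng, 25)
        lhs = compute_mw(s1 + s2)
        rhs = compute_mw(s1) + compute_mw(s2) - 18.0153 / 1000
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_pi_no_ionizable_sidechains_closed_form(self):
        # only termini ionize: pI = (pKa_N + pKa_C) / 2 = (8.6 + 3.6) / 2
        assert compute_pi("GGGG") == pytest.approx(6.1, abs=2e-3)

    def test_pi_basic_peptide_above_7(self):
        assert compute_pi("RRRR") > 7

    def test_pi_matches_grid_search(self, rng):
        from serpinscape.rcl import _net_charge

        seq = random_protein(rng, 50)
        grid = np.arange(0.0, 14.0, 0.0005)
        charges = np.array([_net_charge(seq, ph) for ph in grid])
        crossing = grid[np.argmin(np.abs(charges))]
        assert compute_pi(seq, tol=1e-3) == pytest.approx(crossing, abs=2e-3)


class TestSummarize:
    def _records(self):
        recs = [
            ProteinRecord(id=f"r{i}", sequence="A" * 50, chromosome="chrZ")
            for i in range(3)
        ]
        anns = [annotate_rcl(r) for r in recs]
        return recs, anns

    def test_all_on_one_chromosome(self):
        recs, anns = self._records()
        rep = summarize_family(recs, anns, {"chrZ"})
        assert rep.pct_on_chromosome_set == 100.00
        assert rep.n_records == 3

    def test_permutation_invariance(self, rng):
        recs, _ = gen_serpin_proteins(30, decoy_fraction=0.2, seed=5)
        for i, r in enumerate(recs):
            object.__setattr__(r, "chromosome", f"c{i % 4}")
        anns = [annotate_rcl(r) for r in recs]
        rep1 = summarize_family(recs, anns, {"c0", "c1"})
        order = rng.permutation(len(recs))
        rep2 = summarize_family([recs[i] for i in order],
                                [anns[i] for i in order], {"c0", "c1"})
        assert rep1 == rep2

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            summarize_family([], [], set())


def _dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _codon_safe(rng, n_codons):
    """Random in-frame DNA with no stop codons."""
    from serpinscape._constants import SENSE_CODONS

    return "".join(rng.choice(SENSE_CODONS, size=n_codons))


class TestIsoforms:
    def test_cdna_length_additivity(self, rng):
        shared = [Exon(i, _dna(rng, 118)) for i in range(1, 9)]
        tail = [Exon(10, _dna(rng, 4))]
        variants = [Exon(9, _dna(rng, 100 + 3 * k), variant=True)
                    for k in range(6)]
        model = GeneModel("g", shared + variants + tail)
        isos = assemble_isoforms(model, translate=False)
        assert [i.cdna_length for i in isos] == [1048 + 3 * k for k in range(6)]

    def test_single_variant_is_plain_concatenation(self, rng):
        exons = [Exon(1, _dna(rng, 30)), Exon(2, _dna(rng, 30), variant=True),
                 Exon(3, _dna(rng, 30))]
        model = GeneModel("g", exons)
        (iso,) = assemble_isoforms(model, translate=False)
        assert iso.cdna == exons[0].sequence + exons[1].sequence + exons[2].sequence

    def test_isoform_specificities_follow_variant_p1(self, rng):
        # variant exons encode the hinge + RCL; engineered P1 residues give
        # one chymotrypsin, one trypsin and one elastase isoform
        from serpinscape._constants import GENETIC_CODE

        codon_of = {aa: next(c for c, a in GENETIC_CODE.items() if a == aa)
                    for aa in "EGTALRYV"}
        prefix = Exon(1, _codon_safe(rng, 110))
        variants = []
        for p1 in "YRA":
            hinge = [codon_of[a] for a in "EEGTLAAAA"]
            spacer = [codon_of["L"]] * 7   # P8..P2
            rcl = hinge + spacer + [codon_of[p1]] + [codon_of["L"]] * 2
            tail = [codon_of["V"]] * 28
            variants.append(
                Exon(2, "".join(rcl + tail), variant=True)
            )
        model = GeneModel("iso", [prefix] + variants)
        isos = assemble_isoforms(model)
        classes = [i.annotation.specificity for i in isos]
        assert classes == ["chymotrypsin", "trypsin", "elastase"]
        p1s = [i.annotation.p1_residue for i in isos]
        assert p1s == ["Y", "R", "A"]

    def test_phase_error(self, rng):
        model = GeneModel("g", [Exon(1, _dna(rng, 31)),
                                Exon(2, _dna(rng, 30), variant=True)])
        with pytest.raises(ValueError, match="phase"):
            assemble_isoforms(model, translate=True)

    def test_no_variant_exon_raises(self, rng):
        model = GeneModel("g", [Exon(1, _dna(rng, 30))])
        with pytest.raises(ValueError):
            assemble_isoforms(model)
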