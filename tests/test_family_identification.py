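"""The 5-histidine scanner, profile scanning and the bona-fide filter."""

import numpy as np
import pytest

import loxminer as lm
from loxminer.family_identification import (
    AA_ORDER, FIVE_HIS_OFFSETS, REASON_NO_5HIS, REASON_NO_LOX, REASON_NO_PLAT,
)
from loxminer.io_formats import SequenceRecord as SR

SIGNATURE = "H" + "A" * 4 + "H" + "A" * 4 + "H" + "A" * 17 + "H" + "A" * 8 + "H"


def oracle_scan(seq):
    """Independent sliding-window check of the histidine spacing."""
    found = []
    for start in range(len(seq)):
        window = seq[start:start + 38]
        if len(window) < 38:
            break
        if (window[0] == "H" and window[5] == "H" and window[10] == "H"
                and window[28] == "H" and window[37] == "H"):
            found.append((start + 1, start + 38))
    return found


class TestFiveHisScanner:
    def test_constructed_signature(self):
        hits = lm.scan_five_his(SR("g", "MA" + SIGNATURE, "protein"))
        assert len(hits) == 1
        hit = hits[0]
        assert (hit.aa_start, hit.aa_end) == (3, 40)
        assert hit.width == 38 == lm.FIVE_HIS_SPAN
        assert hit.his_positions == (3, 8, 13, 31, 40)

    def test_poly_alanine_has_no_hits(self):
        assert lm.scan_five_his(SR("g", "A" * 200, "protein")) == []

    def test_matches_sliding_window_oracle_with_planted_signatures(self, rng):
        for _ in range(100):
            n_planted = int(rng.integers(0, 4))
            seq = list("".join(AA_ORDER[i]
                               for i in rng.integers(0, 20, size=600)))
            for _ in range(n_planted):
                start = int(rng.integers(0, 600 - 38))
                seq[start:start + 38] = SIGNATURE
            seq = "".join(seq)
            hits = lm.scan_five_his(SR("g", seq, "protein"))
            assert [(h.aa_start, h.aa_end) for h in hits] == oracle_scan(seq)

    def test_published_signature_intervals_have_width_38(self, domain_table):
        his = domain_table[domain_table["domain"] == "5HIS"]
        assert ((his["aa_end"] - his["aa_start"] + 1) == 38).all()


class TestProfileScan:
    def test_consensus_window_scores_maximum(self, rng):
        motif = lm.motif_from_consensus("m", "ACDEFGHIKL")
        seq = ("".join(AA_ORDER[i] for i in rng.integers(0, 20, size=50))
               + motif.consensus
               + "".join(AA_ORDER[i] for i in rng.integers(0, 20, size=50)))
        motif.threshold = -1e9  # report every window
        hits = lm.scan_profile(SR("g", seq, "protein"), motif)
        best = max(hits, key=lambda h: h.score)
        assert best.aa_start == 51
        assert best.score == pytest.approx(motif.consensus_score)

    def test_uniform_motif_scores_zero_everywhere(self, rng):
        pfm = np.full((10, 20), 1.0 / 20.0)
        motif = lm.ProfileMotif("flat", pfm, threshold=-1.0)
        seq = "".join(AA_ORDER[i] for i in rng.integers(0, 20, size=60))
        hits = lm.scan_profile(SR("g", seq, "protein"), motif)
        assert len(hits) == 60 - 10 + 1
        assert all(h.score == pytest.approx(0.0) for h in hits)

    def test_matches_bruteforce_all_window_scorer(self, rng):
        motif = lm.motif_from_consensus("m", "WYWYWYWYWY", match_prob=0.6)
        motif.threshold = -30.0
        lod = np.log2(motif.pfm / motif.background[None, :])
        for _ in range(10):
            seq = "".join(AA_ORDER[i] for i in rng.integers(0, 20, size=80))
            expected = []
            for s in range(len(seq) - 10 + 1):
                score = sum(lod[k, AA_ORDER.index(seq[s + k])]
                            for k in range(10))
                if score >= -30.0:
                    expected.append((s + 1, pytest.approx(score)))
            hits = lm.scan_profile(SR("g", seq, "protein"), motif)
            assert [(h.aa_start, h.score) for h in hits] == expected

    def test_column_sums_validated(self):
        with pytest.raises(ValueError):
            lm.ProfileMotif("bad", np.full((10, 20), 0.01))


class TestBonaFideFilter:
    def test_fifteen_candidates_six_lacking_lox_gives_nine(self):
        cfg = lm.SimulationConfig(seed=5, n_true_family=9, n_decoys=6,
                                  decoy_modes=("missing-LOX-domain",))
        bundle = lm.generate_genome_bundle(cfg)
        proteins = {r.id: r for r in bundle.proteins}
        assert len(proteins) == 15
        members = lm.bona_fide_filter(sorted(proteins), proteins)
        accepted = [m for m in members if m.bona_fide]
        assert len(accepted) == 9
        rejected = lm.rejection_report(members)
        assert len(rejected) == 6
        assert set(rejected["reason"]) == {REASON_NO_LOX}

    def test_mixed_decoy_modes_match_manifest(self):
        cfg = lm.SimulationConfig(
            seed=6, n_true_family=12, n_decoys=5,
            subfamily_split={"9-LOX": 3, "13-LOX": 9},
            type2_fraction=0.5, n_scaffolds=10,
            decoy_modes=("missing-LOX-domain", "truncated-LOX",
                         "missing-5His"))
        bundle = lm.generate_genome_bundle(cfg)
        proteins = {r.id: r for r in bundle.proteins}
        members = lm.bona_fide_filter(sorted(proteins), proteins)
        truth = set(bundle.manifest[bundle.manifest["role"] == "true"]["gene_id"])
        assert {m.gene_id for m in members if m.bona_fide} == truth
        reasons = {m.gene_id: m.rejection_reason for m in members
                   if not m.bona_fide}
        modes = bundle.manifest.set_index("gene_id")["decoy_mode"]
        for gid, reason in reasons.items():
            expected = {"missing-LOX-domain": REASON_NO_LOX,
                        "truncated-LOX": REASON_NO_LOX,
                        "missing-5His": REASON_NO_5HIS}[modes[gid]]
            assert reason == expected

    def test_domain_table_route_and_monotonicity(self, domain_table):
        members = lm.bona_fide_filter(["SpLOX1"], domains=domain_table)
        assert members[0].bona_fide
        # removing any domain row can only demote, never promote
        for dom in ("PLAT", "LOX", "5HIS"):
            reduced = domain_table[~((domain_table["gene_id"] == "SpLOX1")
                                     & (domain_table["domain"] == dom))]
            (m,) = lm.bona_fide_filter(["SpLOX1"], domains=reduced)
            assert not m.bona_fide
        (m,) = lm.bona_fide_filter(
            ["SpLOX1"],
            domains=domain_table[domain_table["domain"] != "PLAT"])
        assert m.rejection_reason == REASON_NO_PLAT

    def test_no_evidence_is_error(self):
        with pytest.raises(ValueError, match="ghost"):
            lm.bona_fide_filter(["ghost"], proteins={}, domains=None)

    def test_empty_candidate_list(self):
        assert lm.bona_fide_filter([], proteins={}) == []


class TestTransitPeptide:
    def test_all_serine_window_positive(self):
        call = lm.predict_transit_peptide(SR("g", "S" * 80, "protein"))
        assert call.positive and not call.short

    def test_all_glutamate_window_negative(self):
        call = lm.predict_transit_peptide(SR("g", "E" * 80, "protein"))
        assert not call.positive

    def test_short_protein_flagged(self):
        call = lm.predict_transit_peptide(SR("g", "S" * 30, "protein"))
        assert call.short and call.positive

    def test_generator_contract(self, default_bundle, bundle_proteins):
        truth = default_bundle.manifest.set_index("gene_id")
        for gid, row in truth[truth["role"] == "true"].iterrows():
            call = lm.predict_transit_peptide(bundle_proteins[gid])
            assert call.positive == bool(row["transit_peptide"])


class TestSubfamilyAssignment:
    def test_reference_classified_as_itself(self):
        refs = lm.reference_panel()
        member = lm.FamilyMember(gene_id="ref")
        out = lm.assign_subfamily(member, refs[0], refs, transit=False)
        assert out.subfamily == "9-LOX"

    def test_synthetic_members_agree_with_manifest(self, default_bundle,
                                                   bundle_proteins):
        refs = lm.reference_panel()
        truth = default_bundle.manifest.set_index("gene_id")
        for gid, row in truth[truth["role"] == "true"].iterrows():
            member = lm.assign_subfamily(lm.FamilyMember(gene_id=gid),
                                         bundle_proteins[gid], refs)
            assert member.subfamily == row["subfamily"]
            assert member.lox13_type == row["lox13_type"]

    def test_no_references_error(self, bundle_proteins):
        with pytest.raises(ValueError):
            lm.assign_subfamily(lm.FamilyMember(gene_id="x"),
                                list(bundle_proteins.values())[0], [])


class TestSubfamilyRatio:
    @pytest.mark.parametrize("counts,expected", [
        ({"13-LOX": 7, "9-LOX": 2}, 3.50),
        ({"13-LOX": 2, "9-LOX": 2}, 1.00),
    ])
    def test_ratio(self, counts, expected):
        assert lm.subfamily_ratio(counts) == expected

    def test_zero_denominator_is_undefined_not_error(self):
        assert lm.subfamily_ratio({"13-LOX": 4, "9-LOX": 0}) is None

    def test_negative_count_is_error(self):
        with pytest.raises(ValueError):
            lm.subfamily_ratio({"13-LOX": -1, "9-LOX": 2})
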