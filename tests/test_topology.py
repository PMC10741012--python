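"""Disulfide registry, tryptic digestion and monoisotopic mass arithmetic."""

import math

import pytest
from Bio.SeqUtils import molecular_weight
from hypothesis import given, strategies as st

from cysred.constants import CAM_DELTA, NEM_DELTA, formula_mass
from cysred.topology import (
    CAM,
    NEM,
    CysteineSite,
    DefinitionError,
    TopologyError,
    MabDefinition,
    build_disulfide_map,
    class_counts,
    classify_cysteine,
    digest_tryptic,
    example_igg1,
    mz_of,
    peptide_monoisotopic_mass,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestAdductMasses:
    def test_nem_delta_matches_skyline_value(self):
        # N-ethylmaleimide Michael addition adds C6H7NO2
        assert NEM_DELTA == pytest.approx(125.047679, abs=1e-5)

    def test_cam_delta_matches_skyline_value(self):
        # carboxymethylation via sodium iodoacetate adds C2H2O2
        assert CAM_DELTA == pytest.approx(58.005479, abs=1e-5)

    def test_delta_difference_via_independent_elemental_sum(self):
        # independent oracle: C6H7NO2 - C2H2O2 = C4H5N
        diff = formula_mass("C4H5N")
        assert NEM_DELTA - CAM_DELTA == pytest.approx(diff, abs=1e-9)
        assert NEM_DELTA - CAM_DELTA == pytest.approx(67.042200, abs=1e-5)


class TestDisulfideMap:
    def test_canonical_counts(self, bond_map):
        counts = class_counts(bond_map)
        assert counts["intrachain"] == 12
        assert counts["interchain"] == 2
        assert counts["hinge"] == 2
        assert counts["SEFL"] == 2
        # whole-molecule view: 4 interchain (LC-HC + hinge) + 12 intrachain
        assert counts["interchain"] + counts["hinge"] == 4
        canonical = sum(counts[c] for c in ("intrachain", "interchain", "hinge"))
        assert canonical == 16
        assert len(bond_map) == 18  # 16 canonical + 2 SEFL

    def test_without_sefl(self):
        bond_map = build_disulfide_map(example_igg1(include_sefl=False))
        assert len(bond_map) == 16

    def test_every_registered_cysteine_in_exactly_one_bond(self, mab, bond_map):
        seen = [(s.chain, s.position) for b in bond_map for s in b.sites]
        assert len(seen) == len(set(seen)) == len(mab.registry)

    def test_unpaired_cysteine_raises(self):
        mab = MabDefinition("bad", "AAC", "AAA", "kappa",
                            registry=[{"chain": "LC1", "position": 3,
                                       "bond_class": "intrachain", "partner": None}])
        with pytest.raises(TopologyError):
            build_disulfide_map(mab)

    def test_non_cysteine_position_raises(self):
        mab = MabDefinition(
            "bad", "AAA", "AAA", "kappa",
            registry=[{"chain": "LC1", "position": 1, "bond_class": "intrachain",
                       "partner": {"chain": "LC1", "position": 2}}])
        with pytest.raises(DefinitionError):
            build_disulfide_map(mab)

    def test_classification_lookup(self, bond_map):
        assert classify_cysteine(("LC1", 214), bond_map) == "interchain"
        assert classify_cysteine(("HC1", 229), bond_map) == "hinge"
        assert classify_cysteine(("HC2", 22), bond_map) == "intrachain"
        with pytest.raises(KeyError):
            classify_cysteine(("LC1", 1), bond_map)

    def test_counts_invariant_to_chain_copy_permutation(self, mab, bond_map):
        swap = {"LC1": "LC2", "LC2": "LC1", "HC1": "HC2", "HC2": "HC1"}
        permuted = MabDefinition(
            mab.name, mab.lc_sequence, mab.hc_sequence, mab.light_chain_isotype,
            registry=[
                {**e, "chain": swap[e["chain"]],
                 "partner": {"chain": swap[e["partner"]["chain"]],
                             "position": e["partner"]["position"]}}
                for e in mab.registry
            ],
        )
        assert class_counts(build_disulfide_map(permuted)) == class_counts(bond_map)


class TestDigestion:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ACKGCR", ["ACK", "GCR"]),
            ("ACKPGR", ["ACKPGR"]),  # no cleavage before proline
            ("KKK", ["K", "K", "K"]),
        ],
    )
    def test_cleavage_rule(self, seq, expected):
        assert [p.sequence for p in digest_tryptic(seq)] == expected

    def test_short_cysteine_peptide_not_quantifiable(self):
        peps = digest_tryptic("AAAAKGCGK")  # GCGK is 4 residues
        short = [p for p in peps if "C" in p.sequence][0]
        assert len(short.sequence) == 4 and not short.quantifiable

    def test_missed_cleavages(self):
        peps = digest_tryptic("ACKGCRAAA", missed_cleavages=1)
        seqs = {p.sequence for p in peps}
        assert {"ACK", "GCR", "AAA", "ACKGCR", "GCRAAA"} == seqs

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError):
            digest_tryptic("ACXK")

    @given(st.text(alphabet=AA, min_size=1, max_size=60))
    def test_roundtrip_tiles_sequence(self, seq):
        peps = digest_tryptic(seq, missed_cleavages=0)
        assert "".join(p.sequence for p in peps) == seq
        for p in peps:
            assert seq[p.start - 1 : p.end] == p.sequence

    @given(st.text(alphabet=AA, min_size=1, max_size=60),
           st.integers(min_value=0, max_value=3))
    def test_missed_cleavage_span_bound(self, seq, m):
        base_starts = {p.start for p in digest_tryptic(seq, 0)}
        for p in digest_tryptic(seq, m):
            # count fully-cleaved fragment starts inside this peptide
            inside = [s for s in base_starts if p.start <= s <= p.end]
            assert 1 <= len(inside) <= m + 1


class TestMasses:
    def test_bare_cysteine_mass(self):
        assert peptide_monoisotopic_mass("C") == pytest.approx(121.019749, abs=1e-4)

    def test_against_biopython_oracle(self):
        for seq in ("C", "ACDEFGHIK", "WYR", "PEPTIDE"):
            expected = molecular_weight(seq, seq_type="protein", monoisotopic=True)
            assert peptide_monoisotopic_mass(seq) == pytest.approx(expected, abs=1e-3)

    @given(st.text(alphabet=AA, min_size=1, max_size=30))
    def test_nem_additivity(self, seq):
        seq = seq + "C"  # guarantee a cysteine
        plain = peptide_monoisotopic_mass(seq)
        labelled = peptide_monoisotopic_mass(seq, [NEM])
        assert labelled - plain == pytest.approx(NEM_DELTA, abs=1e-12)

    def test_adduct_order_independent(self):
        a = peptide_monoisotopic_mass("CAC", [NEM, CAM])
        b = peptide_monoisotopic_mass("CAC", [CAM, NEM])
        assert a == b

    def test_too_many_adducts(self):
        with pytest.raises(ValueError):
            peptide_monoisotopic_mass("CAK", [NEM, CAM])

    @pytest.mark.parametrize("mass,z,expected", [
        (1000.0, 1, 1001.007276),
        # [M+2H]2+: every charge adds a proton, so M/z + m_p exactly
        (1000.0, 2, 501.007276),
    ])
    def test_mz(self, mass, z, expected):
        assert mz_of(mass, z) == pytest.approx(expected, abs=1e-9)

    def test_mz_zero_charge(self):
        with pytest.raises(ValueError):
            mz_of(1000.0, 0)


def test_cysteine_site_validation():
    with pytest.raises(DefinitionError):
        CysteineSite("XX", 1, "hinge")
    with pytest.raises(DefinitionError):
        CysteineSite("LC1", 1, "weird")
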