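"""Annotation and dN/dS: codon enumeration, strand handling, neutrality."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from mitobottleneck import classify_substitution, compute_dnds, count_potential_sites
from mitobottleneck.annotation import translate_codon
from mitobottleneck.dnds import (
    codon_site_counts,
    random_coding_substitutions,
    vaf_by_region,
)

ALL_CODONS = ["".join(c) for c in product("ACGT", repeat=3)]


class TestAnnotation:
    def test_region_lookup(self, ann):
        assert ann.region_at(100) == "loop"       # control region
        assert ann.region_at(16400) == "loop"
        assert ann.region_at(600) == "tRNA"
        assert ann.region_at(2000) == "rRNA"
        assert ann.region_at(7000) == "coding"    # CO1
        assert ann.region_at(8290) == "loop"      # intergenic spacer

    def test_site_bounds_checked(self, ann):
        with pytest.raises(ValueError):
            ann.region_at(0)
        with pytest.raises(ValueError):
            ann.region_at(16570)

    def test_landmark_reference_bases(self, ann):
        assert ann.base_at(302) == "A" and ann.base_at(309) == "C"
        assert ann.base_at(10304) == "G" and ann.base_at(3243) == "A"

    def test_all_cds_whole_codon_length(self, ann):
        for name, seq in ann.all_cds_sequences().items():
            assert len(seq) % 3 == 0, name
            assert len(seq) > 0

    def test_mito_specific_codons(self):
        assert translate_codon("TGA") == "W"   # Trp, not stop
        assert translate_codon("AGA") == "*"   # stop, not Arg
        assert translate_codon("ATA") == "M"   # Met, not Ile
        with pytest.raises(ValueError):
            translate_codon("NTA")


class TestClassification:
    def test_noncoding_site_gets_region_label(self, ann):
        site = 100
        ref = ann.base_at(site)
        alt = [b for b in "ACGT" if b != ref][0]
        calls = classify_substitution(site, ref, alt, ann)
        assert len(calls) == 1
        assert calls[0].region == "loop" and calls[0].effect is None

    def test_reference_mismatch_names_site(self, ann):
        site = 7000
        wrong = [b for b in "ACGT" if b != ann.base_at(site)][0]
        with pytest.raises(ValueError, match=str(site)):
            classify_substitution(site, wrong, "A" if wrong != "A" else "C", ann)

    def test_forward_strand_effect_matches_manual_codon_edit(self, ann):
        gene = ann.gene("CO1")
        cds = ann.cds_sequence("CO1")
        for pos in (0, 1, 2, 30, 31, 32, 100):
            site = gene["start"] + pos
            ref = ann.base_at(site)
            for alt in "ACGT":
                if alt == ref:
                    continue
                call = [
                    c for c in classify_substitution(site, ref, alt, ann)
                    if c.gene == "CO1"
                ][0]
                ci, off = divmod(pos, 3)
                codon = cds[ci * 3 : ci * 3 + 3]
                mutated = codon[:off] + alt + codon[off + 1 :]
                expected = (
                    "SY" if translate_codon(codon) == translate_codon(mutated) else "NS"
                )
                assert call.effect == expected

    def test_reverse_strand_classified_on_reverse_complement(self, ann):
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        gene = ann.gene("ND6")  # light-strand gene
        cds = ann.cds_sequence("ND6")
        site = gene["end"] - 10  # position 10 of the coding sequence
        ref = ann.base_at(site)
        alt = [b for b in "ACGT" if b != ref][0]
        call = classify_substitution(site, ref, alt, ann)[0]
        ci, off = divmod(10, 3)
        codon = cds[ci * 3 : ci * 3 + 3]
        assert codon[off] == comp[ref]
        mutated = codon[:off] + comp[alt] + codon[off + 1 :]
        expected = (
            "SY" if translate_codon(codon) == translate_codon(mutated) else "NS"
        )
        assert call.effect == expected

    def test_overlapping_genes_reported_per_context(self, ann):
        site = 8550  # inside both ATP8 and ATP6
        ref = ann.base_at(site)
        alt = [b for b in "ACGT" if b != ref][0]
        calls = classify_substitution(site, ref, alt, ann)
        assert {c.gene for c in calls} == {"ATP8", "ATP6"}
        assert all(c.overlapping for c in calls)

    def test_trailing_incomplete_codon_base_has_no_effect_call(self, ann):
        gene = ann.gene("CO3")  # length % 3 == 1: one trailing base
        site = gene["end"]
        ref = ann.base_at(site)
        alt = [b for b in "ACGT" if b != ref][0]
        call = classify_substitution(site, ref, alt, ann)[0]
        assert call.region == "coding" and call.effect is None


class TestPotentialSites:
    def test_tta_enumeration(self):
        assert codon_site_counts("TTA") == (7, 2)  # TTG, CTA synonymous

    def test_conservation_over_all_codons(self):
        for codon in ALL_CODONS:
            ns, sy = codon_site_counts(codon)
            assert ns + sy == 9, codon

    def test_additivity(self):
        n1, s1 = count_potential_sites(["TTAGCA"])
        n2, s2 = count_potential_sites(["TTAGCATTAGCA"])
        assert (n2, s2) == (2 * n1, 2 * s1)

    def test_genome_totals_conserve(self, ann):
        seqs = ann.all_cds_sequences()
        N, S = count_potential_sites(seqs)
        n_codons = sum(len(s) // 3 for s in seqs.values())
        assert N + S == 9 * n_codons

    def test_ambiguous_bases_rejected(self):
        with pytest.raises(ValueError):
            count_potential_sites(["TTN"])
        with pytest.raises(ValueError):
            count_potential_sites(["TTAG"])


class TestDnDs:
    def test_ratio_arithmetic(self, ann):
        from mitobottleneck.dnds import DnDsResult

        r = DnDsResult(stratum="all", n=7, s=2, N=70, S=20)
        assert r.ratio == pytest.approx(1.0)

    def test_no_observed_variants_gives_undefined_ratio(self, ann):
        out = compute_dnds(pd.DataFrame(columns=["site", "ref", "alt"]), ann)
        assert out["n"].iloc[0] == 0 and out["s"].iloc[0] == 0
        assert np.isnan(out["dnds"].iloc[0])

    def test_neutral_input_gives_ratio_near_one(self, ann):
        """Substitutions drawn uniformly over coding sites are split NS/SY
        in proportion to the potential sites, so dN/dS ~ 1 within the
        binomial sampling interval."""
        rng = np.random.default_rng(17)
        n_draws = 4000
        variants = random_coding_substitutions(ann, n_draws, rng)
        out = compute_dnds(variants, ann)
        N, S = out["N"].iloc[0], out["S"].iloc[0]
        p = N / (N + S)
        # duplicates collapse to distinct substitutions, so the binomial
        # denominator is the number of distinct observed variants
        n_distinct = out["n"].iloc[0] + out["s"].iloc[0]
        se = np.sqrt(p * (1 - p) / n_distinct)
        p_hat = out["n"].iloc[0] / n_distinct
        assert abs(p_hat - p) < 3 * se
        assert out["dnds"].iloc[0] == pytest.approx(1.0, abs=0.15)

    def test_strata_partition_observed_counts(self, ann):
        rng = np.random.default_rng(23)
        variants = random_coding_substitutions(ann, 300, rng)
        variants["vaf"] = rng.uniform(0.001, 1.0, len(variants))
        strata = [(0.0, 0.1), (0.1, 0.9), (0.9, 1.0)]
        out = compute_dnds(variants, ann, strata=strata)
        whole = compute_dnds(variants, ann)
        assert (out["n"].sum(), out["s"].sum()) == (
            whole["n"].iloc[0],
            whole["s"].iloc[0],
        )


class TestVafByRegion:
    def test_keys_partition_rows(self, ann):
        rng = np.random.default_rng(29)
        coding = random_coding_substitutions(ann, 40, rng)
        loop_site = 200
        loop_ref = ann.base_at(loop_site)
        rows = [
            {"site": loop_site, "ref": loop_ref,
             "alt": [b for b in "ACGT" if b != loop_ref][0]}
        ]
        variants = pd.concat([coding, pd.DataFrame(rows)], ignore_index=True)
        variants["vaf"] = rng.uniform(0, 1, len(variants))
        out = vaf_by_region(variants, ann)
        assert len(out) == len(variants)
        assert out["key"].notna().all()
        assert set(out["key"]) <= {"NS", "SY", "loop", "tRNA", "rRNA"}
        assert (out.loc[out["site"] == loop_site, "key"] == "loop").all()
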