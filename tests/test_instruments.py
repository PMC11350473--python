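"""Instrument-derivation funnel: region extraction, intersection,
significance filtering, greedy LD clumping and mechanism grouping."""

import io

import numpy as np
import pandas as pd
import pytest

from triomr.errors import InputError, ValidationError
from triomr.instruments import (derive_instruments, extract_region_snvs,
                                filter_genomewide, group_by_mechanism,
                                intersect_datasets, ld_clump,
                                load_gene_regions)
from triomr.pipeline import bundled_gene_regions_path

HEADER = "drug_subclass\tbnf_code\tgene\tchrom\tstart\tend\tmechanism\n"


def stats_frame(rows):
    """rows: (rsid, chrom, pos, pval)."""
    df = pd.DataFrame(rows, columns=["rsid", "chrom", "pos", "pval"])
    df["effect_allele"], df["other_allele"] = "A", "G"
    df["eaf"], df["beta"], df["se"], df["n"] = 0.3, 0.1, 0.02, 1000
    return df


class TestLoadGeneRegions:
    def test_bundled_mapping_parses_with_expected_targets(self):
        regions = load_gene_regions(bundled_gene_regions_path())
        adrb1 = regions[regions["gene"] == "ADRB1"].iloc[0]
        assert adrb1["drug_subclass"] == "Beta-adrenoceptor blocking drugs"
        assert adrb1["bnf_code"] == "2040"
        assert adrb1["chrom"] == "10"
        # the vasodilator subclass maps to two genes with distinct mechanisms
        vaso = regions[regions["drug_subclass"]
                       == "Vasodilator antihypertensive drugs"]
        assert set(vaso["gene"]) == {"EDNRA", "KCNJ11"}
        assert vaso["mechanism"].nunique() == 2

    def test_empty_file_returns_empty_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            regions = load_gene_regions(io.StringIO(HEADER))
        assert regions.empty
        assert any("empty" in r.message for r in caplog.records)

    def test_start_after_end_names_the_row(self):
        body = HEADER + "X\t1\tG1\t1\t100\t50\tm\n"
        with pytest.raises(ValidationError, match="rows: 1"):
            load_gene_regions(io.StringIO(body))

    def test_duplicate_region_rows_rejected(self):
        row = "X\t1\tG1\t1\t100\t200\tm\n"
        with pytest.raises(ValidationError, match="G1"):
            load_gene_regions(io.StringIO(HEADER + row + row))


class TestExtractRegionSnvs:
    regions = pd.DataFrame({
        "drug_subclass": ["S", "S"], "bnf_code": ["1", "1"],
        "gene": ["G1", "G2"], "chrom": ["1", "2"],
        "start": [100, 500], "end": [200, 600],
        "mechanism": ["m1", "m2"],
    })

    def test_boundaries_are_inclusive(self):
        stats = stats_frame([("a", "1", 100, 0.1), ("b", "1", 200, 0.1),
                             ("c", "1", 201, 0.1), ("d", "1", 99, 0.1)])
        kept = extract_region_snvs(stats, self.regions)
        assert sorted(kept["rsid"]) == ["a", "b"]

    def test_matches_brute_force_interval_scan(self):
        rng = np.random.default_rng(1)
        stats = stats_frame([
            (f"s{i}", rng.choice(["1", "2"]), int(rng.integers(1, 1000)), 0.1)
            for i in range(10)
        ])
        kept = set(extract_region_snvs(stats, self.regions)["rsid"])
        expected = set()
        for _, s in stats.iterrows():
            for _, r in self.regions.iterrows():
                if (s["chrom"] == r["chrom"]
                        and r["start"] <= s["pos"] <= r["end"]):
                    expected.add(s["rsid"])
        assert kept == expected

    def test_snv_in_overlapping_regions_annotated_with_each(self):
        overlapping = self.regions.copy()
        overlapping.loc[1, ["chrom", "start", "end"]] = ["1", 150, 250]
        stats = stats_frame([("a", "1", 160, 0.1)])
        kept = extract_region_snvs(stats, overlapping)
        assert len(kept) == 2
        assert set(kept["gene"]) == {"G1", "G2"}


class TestIntersectAndFilter:
    def test_intersection_cases(self):
        stats = stats_frame([(f"s{i}", "1", i, 0.1) for i in range(10)])
        assert intersect_datasets(stats, []).empty
        assert len(intersect_datasets(stats, stats["rsid"])) == 10
        kept = intersect_datasets(stats, [f"s{i}" for i in range(7)])
        assert list(kept["rsid"]) == [f"s{i}" for i in range(7)]  # order kept

    def test_intersection_normalizes_identifiers(self):
        stats = stats_frame([("rs1", "1", 1, 0.1)])
        assert len(intersect_datasets(stats, [" RS1 "])) == 1

    def test_genomewide_threshold_is_strict(self):
        stats = stats_frame([("a", "1", 1, 4.9e-8), ("b", "1", 2, 5e-8),
                             ("c", "1", 3, 1e-3)])
        kept = filter_genomewide(stats)
        assert list(kept["rsid"]) == ["a"]

    def test_filter_count_matches_brute_force(self):
        rng = np.random.default_rng(2)
        pvals = 10.0 ** rng.uniform(-12, 0, size=200)
        stats = stats_frame([(f"s{i}", "1", i + 1, p)
                             for i, p in enumerate(pvals)])
        kept = filter_genomewide(stats, 5e-8)
        assert len(kept) == int((pvals < 5e-8).sum())

    def test_filters_are_idempotent(self):
        stats = stats_frame([(f"s{i}", "1", i + 1, p)
                             for i, p in enumerate([1e-10, 1e-9, 0.5])])
        once = filter_genomewide(stats)
        twice = filter_genomewide(once)
        pd.testing.assert_frame_equal(once, twice)


def _brute_force_clump(snvs, reference, r2_threshold):
    """Step-by-step re-implementation of the greedy definition."""
    remaining = snvs.sort_values(
        ["pval", "chrom", "pos"],
        key=lambda c: c.astype(str) if c.name == "chrom" else c,
    ).to_dict("records")
    kept = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index["rsid"])
        survivors = []
        for cand in remaining:
            x = reference[index["rsid"]].to_numpy(float)
            y = reference[cand["rsid"]].to_numpy(float)
            r2 = np.corrcoef(x, y)[0, 1] ** 2
            if not (cand["chrom"] == index["chrom"]) or np.isnan(r2):
                r2 = 0.0
            if r2 < r2_threshold:
                survivors.append(cand)
        remaining = survivors
    return set(kept)


class TestLdClump:
    def _reference(self, rng, n_snvs, n=400, blocks=None):
        """Reference dosages; `blocks` lists index groups in near-perfect LD."""
        base = rng.integers(0, 3, size=(n, n_snvs)).astype(float)
        if blocks:
            for grp in blocks:
                for j in grp[1:]:
                    base[:, j] = base[:, grp[0]]
        return pd.DataFrame(base, columns=[f"s{i}" for i in range(n_snvs)])

    def test_perfect_ld_keeps_lowest_p(self):
        rng = np.random.default_rng(3)
        ref = self._reference(rng, 2, blocks=[[0, 1]])
        snvs = stats_frame([("s0", "1", 1, 1e-10), ("s1", "1", 2, 1e-9)])
        kept = ld_clump(snvs, ref, 0.01)
        assert list(kept["rsid"]) == ["s0"]

    def test_unlinked_snvs_all_retained(self):
        rng = np.random.default_rng(4)
        ref = self._reference(rng, 5)
        snvs = stats_frame([(f"s{i}", "1", i + 1, 1e-9) for i in range(5)])
        assert len(ld_clump(snvs, ref, 0.5)) == 5

    def test_matches_brute_force_on_random_panels(self):
        """50 random panels of <=12 SNVs: greedy output equals the oracle
        and every retained pair has r^2 below the threshold."""
        rng = np.random.default_rng(5)
        for trial in range(50):
            n_snvs = int(rng.integers(2, 13))
            blocks = [[0, 1]] if n_snvs >= 2 and rng.random() < 0.5 else None
            ref = self._reference(rng, n_snvs, blocks=blocks)
            snvs = stats_frame([
                (f"s{i}", "1", i + 1, float(10 ** rng.uniform(-12, -2)))
                for i in range(n_snvs)
            ])
            thr = float(rng.choice([0.01, 0.1, 0.5]))
            kept = ld_clump(snvs, ref, thr)
            assert set(kept["rsid"]) == _brute_force_clump(snvs, ref, thr)
            for i, a in enumerate(kept["rsid"]):
                for b in kept["rsid"].iloc[i + 1:]:
                    r2 = np.corrcoef(ref[a], ref[b])[0, 1] ** 2
                    assert r2 < thr

    def test_clump_is_idempotent(self):
        rng = np.random.default_rng(6)
        ref = self._reference(rng, 8, blocks=[[0, 1, 2]])
        snvs = stats_frame([(f"s{i}", "1", i + 1, 10.0 ** -(i + 3))
                            for i in range(8)])
        once = ld_clump(snvs, ref, 0.01)
        twice = ld_clump(once, ref, 0.01)
        pd.testing.assert_frame_equal(once, twice)

    def test_missing_reference_snv_named(self):
        rng = np.random.default_rng(7)
        ref = self._reference(rng, 1)
        snvs = stats_frame([("s0", "1", 1, 1e-9), ("absent", "1", 2, 1e-9)])
        with pytest.raises(InputError, match="absent"):
            ld_clump(snvs, ref, 0.01)

    def test_cross_chromosome_pairs_treated_unlinked(self):
        rng = np.random.default_rng(8)
        ref = self._reference(rng, 2, blocks=[[0, 1]])  # numerically identical
        snvs = stats_frame([("s0", "1", 1, 1e-10), ("s1", "2", 1, 1e-9)])
        assert len(ld_clump(snvs, ref, 0.01)) == 2


class TestMechanismGrouping:
    def annotated(self, rows):
        """rows: (rsid, subclass, gene, mechanism)."""
        df = pd.DataFrame(rows, columns=["rsid", "drug_subclass", "gene",
                                         "mechanism"])
        df["bnf_code"], df["chrom"] = "1", "1"
        df["start"], df["end"] = 1, 10
        df["pos"] = range(1, len(df) + 1)
        df["pval"], df["beta"], df["se"], df["eaf"] = 1e-9, 0.1, 0.02, 0.3
        df["effect_allele"], df["other_allele"], df["n"] = "A", "G", 1000
        return df

    def test_shared_mechanism_gives_single_multi_snv_set(self):
        sets = group_by_mechanism(self.annotated([
            ("rs1", "CCB", "CACNB2", "antagonist"),
            ("rs2", "CCB", "CACNB2", "antagonist"),
            ("rs3", "CCB", "CACNB2", "antagonist"),
        ]))
        assert len(sets) == 1 and sets[0].n_snps == 3

    def test_conflicting_mechanisms_split_subclass(self):
        sets = group_by_mechanism(self.annotated([
            ("rs1", "Vasodilator", "EDNRA", "endothelin antagonist"),
            ("rs2", "Vasodilator", "KCNJ11", "potassium channel opener"),
        ]))
        assert len(sets) == 2
        assert all(s.n_snps == 1 for s in sets)
        assert {s.genes for s in sets} == {("EDNRA",), ("KCNJ11",)}
        assert all("conflicting" in s.rationale for s in sets)

    def test_single_snv_single_set(self):
        sets = group_by_mechanism(self.annotated([
            ("rs1", "BB", "ADRB1", "antagonist")]))
        assert len(sets) == 1 and sets[0].snv_ids == ["rs1"]

    def test_missing_mechanism_tag_rejected(self):
        df = self.annotated([("rs1", "BB", "ADRB1", "antagonist")])
        df.loc[0, "mechanism"] = None
        with pytest.raises(InputError, match="rs1"):
            group_by_mechanism(df)


class TestFunnel:
    def test_counts_monotone_and_chained(self, small_panel, small_trios):
        """Each funnel step's input equals the previous step's output and
        never grows."""
        from helpers import make_truth
        from triomr.synthetic_cohort import simulate_exposure_gwas

        region_tsv = io.StringIO(
            HEADER + "S\t1\tG1\t2\t100\t300\tm1\nS2\t2\tG2\t2\t350\t600\tm2\n")
        regions = load_gene_regions(region_tsv)
        truth = make_truth_from_panel(small_panel)
        stats, _ = simulate_exposure_gwas(small_panel, truth, 20_000, seed=21)
        reference = pd.DataFrame(
            np.vstack([small_trios.dosage_m, small_trios.dosage_f]),
            columns=small_trios.snv_ids)
        sets, funnel = derive_instruments(stats, regions, small_trios.snv_ids,
                                          reference)
        steps = funnel.steps
        assert all(s["n_out"] <= s["n_in"] for s in steps[:4])
        for prev, nxt in zip(steps, steps[1:4]):
            assert nxt["n_in"] == prev["n_out"]


def make_truth_from_panel(panel):
    from helpers import make_truth

    class _R:  # tiny adapter: make_truth only needs snv_ids
        snv_ids = panel.snv_ids
    return make_truth(_R, beta_snp=1.0)
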