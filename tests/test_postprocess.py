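"""cis/trans calls, signal grouping, enrichment, Hi-C contacts, eQTM joins."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pewas.catalog import load_eqtm_catalog, load_pqtm_catalog
from pewas.containers import ConfigurationError
from pewas.postprocess import (
    annotation_enrichment,
    classify_cis_trans,
    cross_reactivity_filter,
    eqtm_overlap,
    fisher_enrichment,
    group_signals,
    hic_bin_start,
    hic_contact_enrichment,
)


def fisher_two_sided_oracle(a, b, c, d):
    """Brute-force two-sided Fisher p by hypergeometric enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


class TestCisTrans:
    def test_cpg_inside_gene_interval_is_cis(self):
        row = pd.DataFrame(
            [
                {
                    "cpg_id": "cg10604476", "cpg_chr": "19", "cpg_pos": 10_403_908,
                    "protein_chr": "19", "gene_start": 10_400_657, "gene_end": 10_407_454,
                }
            ]
        )
        assert classify_cis_trans(row).iloc[0] == True  # noqa: E712

    def test_different_chromosome_is_trans(self):
        row = pd.DataFrame(
            [
                {
                    "cpg_id": "cg05575921", "cpg_chr": "5", "cpg_pos": 373_378,
                    "protein_chr": "1", "gene_start": 207_101_863, "gene_end": 207_119_811,
                }
            ]
        )
        assert classify_cis_trans(row).iloc[0] == False  # noqa: E712

    def test_exactly_one_megabase_is_cis_boundary_inclusive(self):
        row = pd.DataFrame(
            [
                {
                    "cpg_id": "cgX", "cpg_chr": "1", "cpg_pos": 1_000,
                    "protein_chr": "1", "gene_start": 1_001_000, "gene_end": 1_002_000,
                }
            ]
        )
        assert classify_cis_trans(row).iloc[0] == True  # noqa: E712
        row["gene_start"] += 1
        assert classify_cis_trans(row).iloc[0] == False  # noqa: E712

    def test_missing_coordinates_marked_untestable(self):
        row = pd.DataFrame(
            [
                {
                    "cpg_id": "cgX", "cpg_chr": None, "cpg_pos": None,
                    "protein_chr": "1", "gene_start": 1, "gene_end": 2,
                }
            ]
        )
        assert classify_cis_trans(row).isna().iloc[0]

    def test_catalog_has_exactly_ten_cis_pqtms(self):
        catalog = load_pqtm_catalog()
        cis = classify_cis_trans(catalog)
        assert int(cis.sum()) == 10
        assert len(catalog) - int(cis.sum()) == 21


class TestGroupSignals:
    def test_catalog_groups_into_nine_signals(self):
        catalog = load_pqtm_catalog()
        groups = group_signals(catalog)
        assert groups.n_components == 9

    def test_nlrc5_component_size(self):
        catalog = load_pqtm_catalog()
        groups = group_signals(catalog)
        nlrc5_cpgs = {"cg07839457", "cg08159663", "cg16411857", "cg00218406", "cg08099136"}
        label = groups.labels[catalog["cpg_id"] == "cg07839457"].iloc[0]
        comp = groups.components.set_index("label").loc[label]
        assert comp["n_edges"] == 14
        assert comp["n_cpgs"] == 5
        assert comp["n_proteins"] == 7
        assert set(groups.labels[catalog["cpg_id"].isin(nlrc5_cpgs)]) == {label}

    def test_single_pair_is_one_component(self):
        df = pd.DataFrame([{"cpg_id": "cgA", "protein_gene": "P1"}])
        groups = group_signals(df)
        assert groups.n_components == 1
        assert groups.components.iloc[0]["n_edges"] == 1

    def test_labels_invariant_to_row_order(self):
        catalog = load_pqtm_catalog()
        shuffled = catalog.sample(frac=1.0, random_state=3)
        g1 = group_signals(catalog)
        g2 = group_signals(shuffled)
        merged = pd.DataFrame(
            {"id": catalog["cpg_id"] + "|" + catalog["protein_gene"], "l1": g1.labels.values}
        ).merge(
            pd.DataFrame(
                {"id": shuffled["cpg_id"] + "|" + shuffled["protein_gene"], "l2": g2.labels.values}
            ),
            on="id",
        )
        assert (merged["l1"] == merged["l2"]).all()

    def test_locus_merge_joins_nearby_cpgs(self):
        df = pd.DataFrame(
            [
                {"cpg_id": "cgA", "cpg_chr": "1", "cpg_pos": 100, "protein_gene": "P1"},
                {"cpg_id": "cgB", "cpg_chr": "1", "cpg_pos": 300, "protein_gene": "P2"},
            ]
        )
        assert group_signals(df).n_components == 2
        assert group_signals(df, locus_merge_bp=1000).n_components == 1


class TestCrossReactivity:
    def test_empty_lists_no_flags(self):
        catalog = load_pqtm_catalog()
        out, summary = cross_reactivity_filter(catalog, [], [])
        assert summary["n_flagged"] == 0
        assert len(out) == len(catalog)  # flag-only, never deletes

    def test_one_flagged_cpg_in_three_pqtms(self):
        catalog = load_pqtm_catalog()
        out, summary = cross_reactivity_filter(catalog, ["cg08159663"], [])
        assert summary["n_flagged"] == 3  # CD48, FCGR3B, LAG3 pairs

    def test_flagged_aptamer_absent_no_flags(self):
        catalog = load_pqtm_catalog()
        out, summary = cross_reactivity_filter(catalog, [], ["9999-99_9"])
        assert summary["n_flagged"] == 0


class TestFisherEnrichment:
    def test_reference_table_odds_ratio_and_oracle_p(self):
        res = fisher_enrichment(10, 90, 10, 890)
        assert res["odds_ratio"] == pytest.approx(9.889, abs=1e-3)
        assert res["p"] == pytest.approx(fisher_two_sided_oracle(10, 90, 10, 890), abs=1e-10)

    def test_equal_rates_or_one_p_one(self):
        res = fisher_enrichment(10, 90, 20, 180)
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        res = fisher_enrichment(0, 10, 5, 85)
        assert res["odds_ratio"] == pytest.approx((0.5 * 85.5) / (10.5 * 5.5))

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(300):
            a, b, c, d = rng.integers(0, 40, size=4)
            res = fisher_enrichment(int(a), int(b), int(c), int(d))
            assert res["p"] == pytest.approx(
                fisher_two_sided_oracle(int(a), int(b), int(c), int(d)), abs=1e-10
            )

    def test_planted_twofold_enhancer_enrichment_recovered(self, rng):
        # background enhancer rate 10%, set rate 20% -> OR ~2.25
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n_bg, n_set = 20_000, 1_000
            manifest = pd.DataFrame(
                {
                    "probe_id": [f"cg{i:06d}" for i in range(n_bg)],
                    "enhancer": r.random(n_bg) < 0.10,
                }
            )
            in_set = r.choice(n_bg, size=n_set, replace=False)
            manifest.loc[in_set, "enhancer"] = r.random(n_set) < 0.20
            cpg_set = set(manifest.loc[in_set, "probe_id"])
            res = annotation_enrichment(cpg_set, manifest, ["enhancer"]).iloc[0]
            hits += 1.6 <= res["odds_ratio"] <= 2.5
        assert hits >= 9

    def test_unknown_category_rejected(self):
        manifest = pd.DataFrame({"probe_id": ["cg1"], "enhancer": [True]})
        with pytest.raises(ConfigurationError):
            annotation_enrichment({"cg1"}, manifest, ["no_such_category"])


def _pqtm_rows(n_cpg=20, n_prot=10, rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for i in range(n_cpg):
        for j in range(n_prot):
            rows.append(
                {
                    "cpg_id": f"cg{i}",
                    "protein_id": f"pr{j}",
                    "cpg_chr": str(1 + i % 5),
                    "cpg_pos": 10_000 + 2_000 * i,
                    "protein_chr": str(1 + j % 4),
                    "gene_start": 5_000_000 + 3_000 * j,
                    "gene_end": 5_000_000 + 3_000 * j + 500,
                }
            )
    return pd.DataFrame(rows)


def _hic_fold_estimate(planted_fold, rng, n_random=200, base_rate=0.15):
    """Simulate a contact map with a planted excess on 98 true pQTM bin
    pairs drawn from an 89-CpG x 15-protein pool, then re-estimate the
    fold with the size-matched randomized background."""
    from pewas.simulate import simulate_hic_map

    pqtms = _pqtm_rows(89, 15)
    true_rows = pqtms.sample(98, random_state=rng.integers(2**31)).reset_index(drop=True)
    cpg_bins = [(x.cpg_chr, hic_bin_start(x.cpg_pos)) for x in pqtms.itertuples()]
    gene_bins = [(x.protein_chr, hic_bin_start(x.gene_start)) for x in pqtms.itertuples()]
    true_pairs = [
        (
            (x.cpg_chr, hic_bin_start(x.cpg_pos)),
            (x.protein_chr, hic_bin_start(x.gene_start)),
        )
        for x in true_rows.itertuples()
    ]
    hic = simulate_hic_map(cpg_bins, gene_bins, true_pairs, base_rate, planted_fold, rng)
    res = hic_contact_enrichment(
        true_rows, hic, n_random=n_random, seed=int(rng.integers(2**31))
    )
    return res.fold


class TestHiC:
    def test_bin_start_alignment(self):
        assert hic_bin_start(1) == 1
        assert hic_bin_start(1000) == 1
        assert hic_bin_start(1001) == 1001
        assert hic_bin_start(10_403_908) == 10_403_001

    def test_saturated_map_fold_one(self):
        pqtms = _pqtm_rows(6, 4).iloc[:10]
        rows = []
        bins = set()
        for r in pqtms.itertuples():
            bins.add((r.cpg_chr, hic_bin_start(r.cpg_pos)))
            bins.add((r.protein_chr, hic_bin_start(r.gene_start)))
        for x in bins:
            for y in bins:
                rows.append((x[0], x[1], y[0], y[1], 1.0))
        hic = pd.DataFrame(
            rows, columns=["chrom_a", "bin_a_start", "chrom_b", "bin_b_start", "contact_value"]
        )
        res = hic_contact_enrichment(pqtms, hic, n_random=100, seed=0)
        assert res.observed_fraction == 1.0
        assert res.fold == pytest.approx(1.0)

    def test_map_of_only_true_pairs_gives_large_fold_min_p(self):
        pqtms = _pqtm_rows(10, 10).iloc[::11]  # 10 diagonal pairs, distinct bins
        rows = [
            (
                r.cpg_chr, hic_bin_start(r.cpg_pos),
                r.protein_chr, hic_bin_start(r.gene_start), 1.0,
            )
            for r in pqtms.itertuples()
        ]
        hic = pd.DataFrame(
            rows, columns=["chrom_a", "bin_a_start", "chrom_b", "bin_b_start", "contact_value"]
        )
        res = hic_contact_enrichment(pqtms, hic, n_random=500, seed=1)
        assert res.observed_fraction == 1.0
        assert res.fold > 3
        assert res.p == pytest.approx(1 / 501)

    def test_empty_map_reports_absent_fold(self):
        res = hic_contact_enrichment(
            _pqtm_rows(3, 3),
            pd.DataFrame(columns=["chrom_a", "bin_a_start", "chrom_b", "bin_b_start", "contact_value"]),
            n_random=10,
        )
        assert res.fold is None and res.p is None

    def test_fold_tracks_planted_excess_on_study_like_geometry(self):
        # 98 true pairs over an 89 x 15 CpG/protein pool; the size-matched
        # background redraws from the observed pools, so a small part of the
        # excess is absorbed into the expectation
        from pewas.simulate import simulate_hic_map

        estimates = {}
        for fold in (1.0, 1.7, 3.0):
            folds = []
            for seed in range(8):
                r = np.random.default_rng(seed)
                folds.append(_hic_fold_estimate(fold, r, n_random=200))
            estimates[fold] = float(np.mean(folds))
        assert abs(estimates[1.0] - 1.0) < 0.15
        assert estimates[1.0] < estimates[1.7] < estimates[3.0]
        assert 1.3 <= estimates[1.7] <= 2.2


class TestEqtmOverlap:
    def test_catalog_join_carries_reported_eqtm(self):
        catalog = load_pqtm_catalog()[["cpg_id", "protein_gene", "p_pqtm", "beta_pqtm"]]
        eqtm = load_eqtm_catalog()
        joined = eqtm_overlap(catalog[catalog["cpg_id"] == "cg08159663"], eqtm)
        assert (joined["gene"] == "NLRC5").all()
        assert joined["eqtm_p"].iloc[0] == pytest.approx(8.26e-10)

    def test_empty_table_no_rows(self):
        catalog = load_pqtm_catalog()
        joined = eqtm_overlap(catalog, pd.DataFrame(columns=["cpg_id", "transcript"]))
        assert joined.empty

    def test_cpg_with_two_transcripts_two_rows(self):
        pqtms = pd.DataFrame([{"cpg_id": "cgA", "protein_id": "p"}])
        eqtm = pd.DataFrame(
            [
                {"cpg_id": "cgA", "transcript": "T1", "eqtm_p": 1e-8, "eqtm_beta": 0.2},
                {"cpg_id": "cgA", "transcript": "T2", "eqtm_p": 1e-5, "eqtm_beta": -0.1},
            ]
        )
        assert len(eqtm_overlap(pqtms, eqtm)) == 2
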