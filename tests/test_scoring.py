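"""Tests for majority vote, discordance rules, tabulation, extrapolation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fishscreen import fixtures as fx
from fishscreen import scoring as sc
from fishscreen import synthetic as syn
from fishscreen.taxonomy import CompartmentTaxonomy


def table_from_votes(mrna_votes, protein_votes=None, gene="g1",
                     tissue="cns", compartment="central_brain_soma"):
    protein_votes = protein_votes if protein_votes is not None else mrna_votes
    rows = [
        dict(
            gene_id=gene, tissue=tissue, compartment=compartment,
            annotator=f"ann{i}", mrna_present=m, protein_present=p,
        )
        for i, (m, p) in enumerate(zip(mrna_votes, protein_votes))
    ]
    return pd.DataFrame(rows)


class TestAggregateMajority:
    def test_unanimous(self):
        calls, conflicts = sc.aggregate_majority(
            table_from_votes([True, True, True])
        )
        assert calls["mrna"].iloc[0] is True or calls["mrna"].iloc[0] == True  # noqa: E712
        assert calls["mrna_resolution"].iloc[0] == "unanimous"
        assert conflicts.empty

    def test_two_one_majority(self):
        calls, _ = sc.aggregate_majority(
            table_from_votes([True, True, False])
        )
        assert bool(calls["mrna"].iloc[0]) is True
        assert calls["mrna_resolution"].iloc[0] == "majority"

    def test_tie_with_na_escalated(self):
        calls, conflicts = sc.aggregate_majority(
            table_from_votes([True, False, pd.NA])
        )
        assert calls["resolution"].iloc[0] == "escalated_unresolved"
        assert len(conflicts) == 1
        assert sc.resolved_calls(calls).empty

    def test_single_non_na_vote_resolves(self):
        calls, _ = sc.aggregate_majority(
            table_from_votes([True, pd.NA, pd.NA])
        )
        assert bool(calls["mrna"].iloc[0]) is True
        assert calls["mrna_resolution"].iloc[0] == "majority"

    def test_fewer_than_three_annotators_error_names_key(self):
        table = table_from_votes([True, True])
        with pytest.raises(ValueError, match="g1"):
            sc.aggregate_majority(table)

    def test_annotator_order_invariance(self):
        t1 = table_from_votes([True, False, True])
        t2 = t1.iloc[[2, 0, 1]].reset_index(drop=True)
        c1, _ = sc.aggregate_majority(t1)
        c2, _ = sc.aggregate_majority(t2)
        pd.testing.assert_frame_equal(c1, c2)

    def test_idempotent_on_unanimous_table(self):
        cfg = syn.AnnotationSimConfig(n_genes=5, annotator_error_rate=0.0, seed=0)
        table, _ = syn.simulate_annotation_table(cfg)
        calls, _ = sc.aggregate_majority(table)
        assert (calls["resolution"] == "unanimous").all()

    def test_duplicate_votes_rejected(self):
        table = table_from_votes([True, True, True])
        dup = pd.concat([table, table.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            sc.aggregate_majority(dup)


class TestAnnotatorAgreement:
    def test_noiseless_zero_disagreement(self):
        cfg = syn.AnnotationSimConfig(n_genes=10, annotator_error_rate=0.0, seed=1)
        table, _ = syn.simulate_annotation_table(cfg)
        report = sc.annotator_agreement(table)
        assert (report.per_annotator["disagreement_rate"] == 0).all()
        assert report.per_question.empty

    def test_error_rate_recovered(self):
        """Simulator parameter recovery within binomial error."""
        eps = 0.05
        cfg = syn.AnnotationSimConfig(
            n_genes=150, annotator_error_rate=eps, seed=2
        )
        table, _ = syn.simulate_annotation_table(cfg)
        report = sc.annotator_agreement(table)
        for _, row in report.per_annotator.iterrows():
            se = np.sqrt(eps * (1 - eps) / row["n_votes"])
            assert abs(row["disagreement_rate"] - eps) < 4 * se + 0.01

    def test_annotator_label_permutation_invariance(self):
        cfg = syn.AnnotationSimConfig(n_genes=20, annotator_error_rate=0.1, seed=3)
        table, _ = syn.simulate_annotation_table(cfg)
        report1 = sc.annotator_agreement(table)
        swapped = table.copy()
        mapping = {"annotator_A": "annotator_B", "annotator_B": "annotator_A"}
        swapped["annotator"] = swapped["annotator"].map(
            lambda a: mapping.get(a, a)
        )
        report2 = sc.annotator_agreement(swapped)
        r1 = report1.per_annotator.set_index("annotator")
        r2 = report2.per_annotator.set_index("annotator")
        assert r1.loc["annotator_A", "n_disagreements"] == (
            r2.loc["annotator_B", "n_disagreements"]
        )
        assert (
            report1.overall_disagreement_rate
            == report2.overall_disagreement_rate
        )


def discordance_truth_table_oracle(ms, mp, ps, pp):
    """Hand-written truth table for one cell class with one soma and one
    periphery compartment: (status_discordant, intercellular, intracellular).
    """
    discordant = (ms != ps) or (mp != pp)
    m_any = ms or mp
    p_any = ps or pp
    inter = m_any != p_any
    intra = m_any and p_any and ((ms, mp) != (ps, pp))
    return discordant, inter, intra


def calls_for_pattern(ms, mp, ps, pp):
    rows = [
        dict(gene_id="g", tissue="t", compartment="central_brain_soma",
             mrna=ms, protein=ps, resolution="unanimous",
             mrna_resolution="unanimous", protein_resolution="unanimous"),
        dict(gene_id="g", tissue="t", compartment="vnc_neuropil",
             mrna=mp, protein=pp, resolution="unanimous",
             mrna_resolution="unanimous", protein_resolution="unanimous"),
    ]
    return pd.DataFrame(rows)


class TestClassifyDiscordance:
    @pytest.mark.parametrize(
        "ms,mp,ps,pp", list(itertools.product([False, True], repeat=4))
    )
    def test_all_16_patterns_match_truth_table(self, ms, mp, ps, pp):
        """Exhaustive oracle over soma/periphery x mrna/protein patterns."""
        calls = calls_for_pattern(ms, mp, ps, pp)
        events = sc.classify_discordance(calls)
        want_disc, want_inter, want_intra = discordance_truth_table_oracle(
            ms, mp, ps, pp
        )
        ev = events.iloc[0]
        assert (ev["status"] == "discordant") == want_disc
        assert bool(ev["intercellular"]) == want_inter
        assert bool(ev["intracellular"]) == want_intra
        # invariant: type is none iff concordant
        assert (ev["discordance_type"] == "none") == (not want_disc)

    def test_concordant_everywhere(self):
        events = sc.classify_discordance(calls_for_pattern(True, True, True, True))
        assert events["status"].iloc[0] == "concordant"
        assert events["discordance_type"].iloc[0] == "none"

    def test_mrna_everywhere_protein_nowhere_intercellular(self):
        events = sc.classify_discordance(
            calls_for_pattern(True, True, False, False)
        )
        assert events["discordance_type"].iloc[0] == "intercellular"

    def test_protein_reaches_periphery_without_local_mrna_intracellular(self):
        events = sc.classify_discordance(
            calls_for_pattern(True, False, True, True)
        )
        assert events["discordance_type"].iloc[0] == "intracellular"

    def test_peripheral_mrna_flags(self):
        calls = calls_for_pattern(False, True, False, True)
        events = sc.classify_discordance(calls)
        assert bool(events["peripheral_mrna_neuron"].iloc[0])
        assert not bool(events["peripheral_mrna_glia"].iloc[0])

    def test_within_subregion_population_mismatch_is_intercellular(self):
        # mRNA in one neuronal soma population, protein in another
        rows = [
            dict(gene_id="g", tissue="t", compartment="central_brain_soma",
                 mrna=True, protein=False, resolution="unanimous",
                 mrna_resolution="unanimous", protein_resolution="unanimous"),
            dict(gene_id="g", tissue="t", compartment="neuroblast_lineage",
                 mrna=False, protein=True, resolution="unanimous",
                 mrna_resolution="unanimous", protein_resolution="unanimous"),
        ]
        events = sc.classify_discordance(pd.DataFrame(rows))
        ev = events.iloc[0]
        assert ev["status"] == "discordant"
        assert ev["discordance_type"] == "intercellular"

    def test_unresolved_keys_excluded(self):
        calls = calls_for_pattern(True, True, False, False)
        calls.loc[1, "resolution"] = "escalated_unresolved"
        events = sc.classify_discordance(calls)
        assert len(events) == 1  # soma-only evidence still classified

    def test_parameter_recovery_headline_within_2_points(self):
        """Synthetic tables at eps=0.05: recovered headline discordance
        within +/- 2 percentage points of the generating truth.

        Priors mirror the discordance-heavy regime of a real screen; with
        mostly-concordant priors the any-of-26-calls statistic is inflated
        by vote noise beyond 2 points (binomially unavoidable).
        """
        priors = {
            "concordant": 0.04, "intercellular": 0.48,
            "intracellular": 0.45, "silent": 0.03,
        }
        diffs = []
        for seed in range(5):
            cfg = syn.AnnotationSimConfig(
                n_genes=200, annotator_error_rate=0.05, seed=seed,
                pattern_priors=priors,
            )
            table, truth = syn.simulate_annotation_table(cfg)
            calls, _ = sc.aggregate_majority(table)
            events = sc.classify_discordance(calls)
            profiles = sc.gene_discordance_profiles(events)
            recovered = 100.0 * profiles["any_discordance"].mean()
            true_frac = 100.0 * np.mean(
                [c in ("intercellular", "intracellular")
                 for c in truth.gene_classes.values()]
            )
            diffs.append(abs(recovered - true_frac))
        assert np.mean(diffs) <= 2.0


class TestTabulateExpression:
    def test_percentages_sum_to_100(self):
        cfg = syn.AnnotationSimConfig(n_genes=40, seed=4)
        table, _ = syn.simulate_annotation_table(cfg)
        calls, _ = sc.aggregate_majority(table)
        summary = sc.tabulate_expression(calls)
        pct_cols = [f"pct_{c}" for c in sc.FOUR_CATEGORIES]
        sums = summary.per_compartment[pct_cols].sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-9)
        n_cols = [f"n_{c}" for c in sc.FOUR_CATEGORIES]
        assert (
            summary.per_compartment[n_cols].sum(axis=1)
            == summary.per_compartment["n_genes"]
        ).all()

    def test_fixture_headline_97_5_percent(self):
        table, _ = fx.build_screen_annotation_table()
        calls, _ = sc.aggregate_majority(table)
        summary = sc.tabulate_expression(calls)
        assert summary.headline["any_discordance_percent"] == pytest.approx(97.5)

    def test_category_counts_equal_bruteforce_recount(self):
        """Oracle: exhaustive recount over a random boolean fixture."""
        rng = np.random.default_rng(11)
        rows = []
        for g in range(30):
            for comp in ("central_brain_soma", "psd"):
                m, p = bool(rng.integers(2)), bool(rng.integers(2))
                for ann in range(3):
                    rows.append(
                        dict(gene_id=f"g{g}", tissue="t", compartment=comp,
                             annotator=f"a{ann}", mrna_present=m,
                             protein_present=p)
                    )
        table = pd.DataFrame(rows)
        calls, _ = sc.aggregate_majority(table)
        summary = sc.tabulate_expression(calls)
        res = sc.resolved_calls(calls)
        for _, row in summary.per_compartment.iterrows():
            sub = res[res["compartment"] == row["compartment"]]
            m = sub["mrna"].astype(bool)
            p = sub["protein"].astype(bool)
            assert row["n_both"] == int((m & p).sum())
            assert row["n_mrna_only"] == int((m & ~p).sum())
            assert row["n_protein_only"] == int((~m & p).sum())
            assert row["n_neither"] == int((~m & ~p).sum())


class TestUpsetCounts:
    def test_single_gene_all_compartments(self):
        rows = []
        for comp in ("central_brain_soma", "psd", "vnc_neuropil"):
            for ann in range(3):
                rows.append(
                    dict(gene_id="g0", tissue="t", compartment=comp,
                         annotator=f"a{ann}", mrna_present=True,
                         protein_present=True)
                )
        calls, _ = sc.aggregate_majority(pd.DataFrame(rows))
        patterns, marginals = sc.upset_counts(calls, "mrna")
        assert len(patterns) == 1
        assert patterns["n_genes"].iloc[0] == 1
        assert (marginals == 1).all()

    def test_random_matrix_matches_bruteforce_enumeration(self):
        """Oracle: enumeration over all 2^k patterns."""
        rng = np.random.default_rng(5)
        comps = ("central_brain_soma", "psd", "vnc_neuropil", "muscle_nucleus")
        rows = []
        for g in range(50):
            for comp in comps:
                val = bool(rng.integers(2))
                for ann in range(3):
                    rows.append(
                        dict(gene_id=f"g{g:02d}", tissue="t", compartment=comp,
                             annotator=f"a{ann}", mrna_present=val,
                             protein_present=val)
                    )
        calls, _ = sc.aggregate_majority(pd.DataFrame(rows))
        patterns, marginals = sc.upset_counts(calls, "mrna")
        membership = (
            sc.resolved_calls(calls)
            .pivot_table(index="gene_id", columns="compartment",
                         values="mrna", aggfunc="max")
            .astype(bool)
        )
        oracle = sc.enumerate_upset_oracle(membership)
        comp_order = list(membership.columns)
        got = {
            tuple(bool(row[c]) for c in comp_order): int(row["n_genes"])
            for _, row in patterns.iterrows()
        }
        assert got == oracle
        # marginals equal column sums (conservation)
        assert (marginals == membership.sum(axis=0)).all()

    def test_pattern_counts_sum_to_gene_total(self):
        table, _ = fx.build_screen_annotation_table(
            n_genes=60, n_discordant=58, n_mb_protein=28,
            n_mb_protein_with_mrna=9, n_mb_mrna_total=20,
            n_mb_ol_mrna_overlap=8, n_nmj_glia=6, n_homozygous_viable=39,
        )
        calls, _ = sc.aggregate_majority(table)
        patterns, _ = sc.upset_counts(calls, "protein")
        assert patterns["n_genes"].sum() == 60


class TestNeuroblastClassification:
    def make_panel(self, mrna_on, prot_on):
        n = len(mrna_on)
        return pd.DataFrame(
            dict(
                cell_id=[f"c{i}" for i in range(n)],
                cell_type=["neuroblast"] + ["progeny"] * (n - 1),
                mrna_count=[8 if m else 0 for m in mrna_on],
                protein_intensity=[100.0 if p else 10.0 for p in prot_on],
                has_transcription_focus=mrna_on,
            )
        )

    def test_all_zero_not_detected(self):
        panel = self.make_panel([False] * 10, [False] * 10)
        out = sc.classify_neuroblast_pattern(panel)
        assert out.pattern_class == "not_detected"

    def test_all_on_homogeneous(self):
        panel = self.make_panel([True] * 10, [True] * 10)
        out = sc.classify_neuroblast_pattern(panel)
        assert out.pattern_class == "homogeneous"

    def test_matched_subset_transcriptional(self):
        on = [True] * 5 + [False] * 5
        out = sc.classify_neuroblast_pattern(self.make_panel(on, on))
        assert out.pattern_class == "cell_specific_transcriptional"

    def test_broad_mrna_restricted_protein_posttranscriptional(self):
        mrna = [True] * 10
        prot = [True] * 2 + [False] * 8
        out = sc.classify_neuroblast_pattern(self.make_panel(mrna, prot))
        assert out.pattern_class == "cell_specific_posttranscriptional"

    def test_too_few_cells_error(self):
        panel = self.make_panel([True] * 4, [True] * 4)
        with pytest.raises(ValueError):
            sc.classify_neuroblast_pattern(panel)

    def test_panel_recovery_noiseless_exact(self):
        panels, labels = fx.build_neuroblast_panels()
        result = sc.classify_neuroblast_panel(panels)
        pred = dict(zip(result["gene_id"], result["pattern_class"]))
        assert pred == labels

    def test_panel_recovery_with_noise(self):
        cfg = syn.NeuroblastSimConfig(
            n_genes=200, presence_flip_rate=0.05, seed=6
        )
        panels, labels = syn.simulate_neuroblast_panel(cfg)
        result = sc.classify_neuroblast_panel(panels)
        pred = dict(zip(result["gene_id"], result["pattern_class"]))
        accuracy = np.mean([pred[g] == c for g, c in labels.items()])
        assert accuracy >= 0.9


class TestExtrapolateGenome:
    def test_reference_case_12_of_200(self):
        out = sc.extrapolate_genome(12, 200, 13_900)
        assert out.estimate == pytest.approx(834.0)
        assert out.lower >= 500.0
        assert out.lower < out.estimate < out.upper

    def test_k_zero(self):
        out = sc.extrapolate_genome(0, 200, 13_900)
        assert out.estimate == 0.0
        assert out.lower == 0.0

    def test_k_equals_n(self):
        out = sc.extrapolate_genome(200, 200, 13_900)
        assert out.estimate == 13_900.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sc.extrapolate_genome(5, 0)
        with pytest.raises(ValueError):
            sc.extrapolate_genome(10, 5)
        with pytest.raises(ValueError):
            sc.extrapolate_genome(1, 5, genome_protein_coding=0)


class TestMdvExport:
    def test_one_row_per_gene_with_compartment_columns(self):
        table, meta = fx.build_screen_annotation_table(
            n_genes=20, n_discordant=19, n_mb_protein=9,
            n_mb_protein_with_mrna=3, n_mb_mrna_total=7,
            n_mb_ol_mrna_overlap=3, n_nmj_glia=2, n_homozygous_viable=13,
        )
        calls, _ = sc.aggregate_majority(table)
        events = sc.classify_discordance(calls)
        profiles = sc.gene_discordance_profiles(events)
        out, schema = sc.export_mdv(calls, profiles, meta)
        assert len(out) == 20
        assert "mrna__central_brain_soma" in out.columns
        assert "homozygous_viable" in out.columns
        assert schema["n_rows"] == 20


class TestTaxonomy:
    def test_every_label_has_class_and_subregion(self):
        tax = CompartmentTaxonomy()
        for label in tax.labels:
            assert tax.cell_class_of[label] in ("neuron", "glia", "muscle")
            assert tax.subregion_of[label] in ("soma", "periphery")

    def test_mismatched_maps_rejected(self):
        with pytest.raises(ValueError):
            CompartmentTaxonomy(
                cell_class_of={"a": "neuron"}, subregion_of={}
            )
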