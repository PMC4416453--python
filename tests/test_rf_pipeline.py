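"""Pipeline tests on the packaged fixture and on synthetic tables."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from randflora import bd_moments as bdm
from randflora import cli, rf_pipeline as rp
from randflora.errors import DomainError, TableError


@pytest.fixture(scope="module")
def table():
    return rp.default_lineage_table()


@pytest.fixture(scope="module")
def stages():
    return rp.default_stage_table()


class TestLoadLineageTable:
    def test_fixture_loads_with_21_disjunctions(self, table):
        assert len(table.disjunctions) == 21
        assert set(table.disjunctions["split_type"]) == {"W-E", "W-E&S", "E-S"}

    def test_fixture_crown_stem_pairs_intact(self, table):
        cicer = table.row("D09")
        assert cicer["crown_age_ma"] == 3.4
        assert cicer["stem_age_ma"] == 12.2
        sider = table.row("D20")
        assert sider["crown_age_ma"] == 17.4
        assert sider["stem_age_ma"] == 47.3

    def test_empty_table_rejected(self):
        header = "\t".join(rp._COLUMNS)
        with pytest.raises(TableError, match="no records"):
            rp.load_lineage_table(header + "\n")

    def _row(self, **kw):
        base = dict(
            row_id="X1", parent_id="NA", kind="disjunction", lineage="L",
            name="X", level="disjunct-clade", split_type="W-E", age_ma="5",
            crown_age_ma="NA", stem_age_ma="NA", n_species="3", source_note="t",
        )
        base.update(kw)
        header = "\t".join(rp._COLUMNS)
        return header + "\n" + "\t".join(str(base[c]) for c in rp._COLUMNS) + "\n"

    def test_unknown_split_type_rejected(self):
        with pytest.raises(TableError, match="split_type"):
            rp.load_lineage_table(self._row(split_type="N-S"))

    def test_broken_nesting_link_rejected(self):
        with pytest.raises(TableError, match="nesting link"):
            rp.load_lineage_table(self._row(parent_id="NOPE"))

    def test_negative_age_rejected(self):
        with pytest.raises(TableError):
            rp.load_lineage_table(self._row(age_ma="-4", crown_age_ma="NA"))

    def test_stem_must_exceed_crown(self):
        with pytest.raises(TableError, match="stem"):
            rp.load_lineage_table(self._row(crown_age_ma="6", stem_age_ma="5"))


class TestRateTable:
    def test_cardinality(self, table):
        rates = rp.compute_rate_table(table, epsilons=(0.0, 0.5, 0.9), basis="both")
        assert len(rates) == len(table.df) * 3 * 2
        per_row = rates.groupby(["row_id", "basis"]).size()
        assert (per_row == 3).all()

    def test_two_taxon_rows_get_nonzero_crown_rates(self, table):
        rates = rp.compute_rate_table(table, epsilons=(0.0,), basis="crown")
        sider = rates[(rates.row_id == "D20") & (rates.epsilon == 0.0)].iloc[0]
        assert sider["n"] == 2.01
        assert sider["r_hat"] == pytest.approx(math.log(2.01 / 2) / 17.4)
        assert sider["r_hat"] > 0

    def test_stem_rate_below_crown_rate_for_older_stem_age(self, table):
        """Same richness over the (older) stem age gives the lower estimate.

        Holds whenever ln(n) / t_stem < ln(n/2) / t_crown, i.e. for clades of
        ordinary richness; two-taxon clades invert it because their adjusted
        crown rate ln(2.01/2)/t is nearly zero by construction.
        """
        rates = rp.compute_rate_table(table, epsilons=(0.0,), basis="both")
        cicer = rates[rates.row_id == "C_CIC"].set_index("basis")
        assert cicer.loc["stem", "r_hat"] < cicer.loc["crown", "r_hat"]

    def test_rows_without_stem_age_are_flagged_not_dropped(self, table):
        rates = rp.compute_rate_table(table, epsilons=(0.0,), basis="stem")
        d15 = rates[rates.row_id == "D15"].iloc[0]
        assert math.isnan(d15["r_hat"]) if d15["r_hat"] is not None else True
        assert "missing stem age" in d15["note"]


class TestReferenceEnvelope:
    def test_asteraceae_selected_at_every_epsilon(self, table):
        envs = rp.reference_envelope(table)
        assert set(envs) == {0.0, 0.5, 0.9}
        for env in envs.values():
            assert env.reference == "Asteraceae"

    def test_single_family_table_uses_that_family(self):
        df = rp.default_lineage_table().df
        keep = df[df["row_id"].isin(["F_SAP", "C_SID", "D20"])]
        text = keep.to_csv(sep="\t", index=False, na_rep="NA")
        tab = rp.load_lineage_table(text)
        envs = rp.reference_envelope(tab, epsilons=(0.0,))
        assert envs[0.0].reference == "Sapotaceae"

    def test_high_extinction_widens_envelope(self, table):
        envs = rp.reference_envelope(table)
        t = np.searchsorted(envs[0.0].times, 10.0)
        ratio0 = envs[0.0].upper[t] / envs[0.0].lower[t]
        ratio9 = envs[0.9].upper[t] / envs[0.9].lower[t]
        assert ratio9 > ratio0

    def test_no_family_rows_is_an_error(self, table):
        df = table.df[table.df["level"] != "family"].copy()
        df["parent_id"] = np.where(
            df["parent_id"].isin(table.families["row_id"]), np.nan, df["parent_id"]
        )
        tab = rp.LineageTable(df)
        with pytest.raises(TableError, match="family"):
            rp.reference_envelope(tab)


class TestClassification:
    @pytest.fixture()
    def crown_cls(self, table):
        envs = rp.reference_envelope(table)
        return rp.classify_clades(table, envs, basis="crown")

    def test_depauperate_old_disjunctions_fall_below(self, crown_cls):
        """Old species-poor splits sit under the no-extinction envelope."""
        sub = crown_cls[(crown_cls.epsilon == 0.0)].set_index("row_id")
        for rid in ("D20", "D15", "D19"):  # Sideroxylon, Canarina, Hypericum
            assert sub.loc[rid, "position"] == "below"

    def test_species_rich_young_disjunctions_fall_above(self, crown_cls):
        sub = crown_cls[(crown_cls.epsilon == 0.0)].set_index("row_id")
        for rid in ("D08", "D10", "D06"):  # Aeonium, Adenocarpus, Campanula
            assert sub.loc[rid, "position"] == "above"

    def test_sideroxylon_below_even_at_high_extinction(self, crown_cls):
        sub = crown_cls[crown_cls.row_id == "D20"].set_index("epsilon")
        assert (sub["position"] == "below").all()

    def test_boundary_value_classifies_within(self, table):
        envs = rp.reference_envelope(table, epsilons=(0.0,))
        env = envs[0.0]
        t = 6.0
        lower, upper = rp._bounds_at(env, t)
        df = table.df.copy()
        df["n_species"] = df["n_species"].astype(float)
        df.loc[df["row_id"] == "D14", "n_species"] = lower  # exactly on the bound
        out = rp.classify_clades(rp.LineageTable(df), envs, basis="crown")
        row = out[(out.row_id == "D14")].iloc[0]
        assert row["position"] == "within"

    def test_row_order_invariance(self, table):
        envs = rp.reference_envelope(table)
        base = rp.classify_clades(table, envs).sort_values(
            ["row_id", "epsilon"]).reset_index(drop=True)
        shuffled = rp.LineageTable(
            table.df.sample(frac=1.0, random_state=5).reset_index(drop=True)
        )
        again = rp.classify_clades(shuffled, envs).sort_values(
            ["row_id", "epsilon"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(base, again)

    def test_age_beyond_grid_is_an_error(self, table):
        envs = rp.reference_envelope(table, times=np.linspace(0.5, 10, 20))
        with pytest.raises(DomainError, match="grid"):
            rp.classify_clades(table, envs, basis="crown")


class TestCladeProbability:
    def test_two_taxon_crown_probability_is_one(self, table):
        probs = rp.clade_probability(table, basis="crown")
        sub = probs[probs.row_id == "D20"]
        assert (sub["probability"] == 1.0).all()

    def test_probabilities_decrease_with_clade_size(self, table):
        df = table.df.copy()
        out = []
        for n in (5, 10, 20):
            df.loc[df["row_id"] == "D14", "n_species"] = n
            probs = rp.clade_probability(rp.LineageTable(df), basis="crown")
            out.append(
                probs[(probs.row_id == "D14") & (probs.epsilon == 0.0)][
                    "probability"
                ].iloc[0]
            )
        assert out[0] > out[1] > out[2]

    def test_all_disjunctions_covered(self, table):
        probs = rp.clade_probability(table)
        assert set(probs["row_id"]) == set(table.disjunctions["row_id"])


class TestGaps:
    def test_fixture_gaps(self, table):
        gaps = rp.stem_crown_gap(table).set_index("row_id")
        assert gaps.loc["D20", "gap_myr"] == pytest.approx(29.9)
        assert bool(gaps.loc["D20", "flagged"])
        assert gaps.loc["D17", "gap_myr"] == pytest.approx(12.5)
        assert bool(gaps.loc["D17", "flagged"])
        assert gaps.loc["D12", "gap_myr"] == pytest.approx(4.7)
        assert not gaps.loc["D12", "flagged"]

    def test_sorted_descending(self, table):
        gaps = rp.stem_crown_gap(table)
        assert (gaps["gap_myr"].diff().dropna() <= 0).all()

    def test_near_zero_gap_not_flagged(self):
        base = rp.default_lineage_table().df
        df = base[base["row_id"].isin(["F_SAP", "C_SID", "D20"])].copy()
        df.loc[df["row_id"] == "D20", "stem_age_ma"] = 17.4 + 1e-9
        gaps = rp.stem_crown_gap(rp.LineageTable(df))
        row = gaps.set_index("row_id").loc["D20"]
        assert row["gap_myr"] == pytest.approx(0.0, abs=1e-6)
        assert not row["flagged"]


class TestStages:
    @pytest.mark.parametrize(
        "age, stage",
        [
            (17.4, "Burdigalian"),
            (11.0, "Tortonian"),
            (6.5, "Messinian"),
            (4.0, "Pliocene"),
            (5.333, "Pliocene"),  # half-open: younger bound belongs below
            (2.58, "Pleistocene"),
            (1.0, "Pleistocene"),
        ],
    )
    def test_assign_stage(self, stages, age, stage):
        assert rp.assign_stage(age, stages).stage == stage

    def test_out_of_span_error(self, stages):
        with pytest.raises(TableError, match="span"):
            rp.assign_stage(47.3, stages)

    def test_snap_tolerance_flags_boundaries(self, stages):
        near = rp.assign_stage(7.5, stages, snap_tol=0.3)
        assert near.stage == "Tortonian" and near.boundary_flag
        far = rp.assign_stage(9.0, stages, snap_tol=0.3)
        assert not far.boundary_flag

    def test_every_disjunction_gets_exactly_one_stage(self, table, stages):
        tl = rp.timeline(table, stages)
        assert len(tl) == 21
        assert tl["stage"].notna().all()
        assert set(tl["stage"]) <= set(stages.df["stage"])

    def test_malformed_stage_tables_rejected(self):
        with pytest.raises(TableError, match="contiguous"):
            rp.load_stage_table(
                "stage\tolder_ma\tyounger_ma\nA\t10\t5\nB\t4\t1\n"
            )
        with pytest.raises(TableError, match="decreasing"):
            rp.load_stage_table("stage\tolder_ma\tyounger_ma\nA\t5\t10\n")


class TestEnvelopeCalibration:
    def test_synthetic_clades_outside_own_rate_envelope_near_5pct(self):
        """~5% of clades simulated at a known rate leave their own envelope."""
        from randflora import bd_sim

        r, eps, t = 0.3, 0.0, 10.0
        p = bdm.BDParams.from_net(r, eps)
        scn = bd_sim.SimScenario(
            lambda_=p.lambda_, mu_background=p.mu, horizon=t,
            condition="crown_survival", seed=7,
        )
        res, _ = bd_sim.simulate_ensemble(scn, 2000)
        counts = np.array([x.extant_count for x in res])
        env = bdm.diversity_limits(r, eps, [t], conf=0.95, basis="crown")
        lo, up = env.lower[0], env.upper[0]
        outside = float(np.mean((counts < lo) | (counts > up)))
        beta = bdm.geometric_law(r, eps, t).beta
        exact = (1.0 - bdm.crown_tail(math.ceil(lo), beta)) + bdm.crown_tail(
            math.floor(up) + 1, beta
        )
        se = math.sqrt(exact * (1 - exact) / counts.size)
        assert 0.02 < exact < 0.08  # ~5% up to clade-size discreteness
        assert abs(outside - exact) <= 3 * se


class TestCLI:
    def _run(self, *args):
        return CliRunner().invoke(cli.main, list(args), catch_exceptions=False)

    def test_rates_subcommand(self, tmp_path):
        out = tmp_path / "rates.tsv"
        result = self._run("rates", "--epsilon", "0,0.5", "--basis", "crown",
                           "--out", str(out))
        assert result.exit_code == 0
        df = pd.read_csv(out, sep="\t")
        assert len(df) == 54 * 2

    def test_timeline_subcommand(self):
        result = self._run("timeline")
        assert result.exit_code == 0
        df = pd.read_csv(io.StringIO(result.output), sep="\t")
        assert len(df) == 21
        assert "Burdigalian" in set(df["stage"])

    def test_classify_subcommand(self):
        result = self._run("classify", "--epsilon", "0")
        assert result.exit_code == 0
        df = pd.read_csv(io.StringIO(result.output), sep="\t")
        assert {"below", "within", "above"} >= set(df["position"])

    def test_simulate_subcommand_deterministic(self):
        args = ("simulate", "--lam", "0.3", "--mu", "0.1", "--time", "10",
                "--condition", "stem_survival", "--reps", "50", "--seed", "4")
        a, b = self._run(*args), self._run(*args)
        assert a.exit_code == 0
        assert a.output == b.output

    def test_extract_subcommand(self, tmp_path, balanced_newick):
        tree = tmp_path / "tree.nwk"
        tree.write_text(balanced_newick)
        (tmp_path / "a.txt").write_text("A\nB\n")
        (tmp_path / "b.txt").write_text("C\nD\n")
        result = self._run(
            "extract", "--tree", str(tree), "--side-a", str(tmp_path / "a.txt"),
            "--side-b", str(tmp_path / "b.txt"), "--split-type", "E-S",
        )
        assert result.exit_code == 0
        df = pd.read_csv(io.StringIO(result.output), sep="\t")
        assert df["age_ma"].iloc[0] == pytest.approx(10.0)

    def test_validation_error_exit_code(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("\t".join(rp._COLUMNS) + "\n")
        result = CliRunner().invoke(cli.main, ["rates", "--table", str(bad)])
        assert result.exit_code == cli.VALIDATION_EXIT
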