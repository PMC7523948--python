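"""Length -> mass -> energy conversion chain and taxonomic fallback."""

import numpy as np
import pandas as pd
import pytest

import foodwebkit as fwk
from foodwebkit.data_model import RANKS
from foodwebkit.energetics import EnergeticsError, EnergyFactor, MassRegression


class TestIndividualEnergy:
    @pytest.mark.parametrize("a,b,ed,L,dm,joules", [
        (1.0, 2.0, 1.0, 3.0, 9.0, 9.0),
        (0.001, 3.0, 23.0, 10.0, 1.0, 23.0),
    ])
    def test_power_law_arithmetic(self, a, b, ed, L, dm, joules):
        reg = MassRegression(metric="total_length", a=a, b=b)
        ef = EnergyFactor(energy_density=ed)
        got_dm, got_j = fwk.individual_energy(L, reg, ef)
        assert got_dm == pytest.approx(dm)
        assert got_j == pytest.approx(joules)

    def test_matches_log_space_evaluation(self, rng):
        for _ in range(1000):
            a = rng.uniform(1e-4, 1e-1)
            b = rng.uniform(0.5, 3.5)
            ed = rng.uniform(5, 40)
            L = rng.uniform(0.5, 40)
            reg = MassRegression(metric="total_length", a=a, b=b)
            _, j = fwk.individual_energy(L, reg, EnergyFactor(energy_density=ed))
            oracle = np.exp(np.log(a) + b * np.log(L)) * ed
            assert j == pytest.approx(oracle, rel=1e-9)

    def test_energy_monotone_in_length(self):
        reg = MassRegression(metric="total_length", a=0.01, b=2.5)
        ef = EnergyFactor(energy_density=20.0)
        js = [fwk.individual_energy(L, reg, ef)[1]
              for L in np.linspace(0.5, 20, 50)]
        assert np.all(np.diff(js) > 0)

    def test_wet_mass_pathway(self):
        reg = MassRegression(metric="total_length", a=1.0, b=1.0)
        ef = EnergyFactor(energy_density=2.0, percent_dry_mass=0.5,
                          basis="wet")
        # DM 4 mg -> wet 8 mg -> 16 J
        assert fwk.individual_energy(4.0, reg, ef)[1] == pytest.approx(16.0)

    def test_metric_mismatch_rejected(self):
        reg = MassRegression(metric="total_length", a=1.0, b=1.0)
        with pytest.raises(EnergeticsError, match="metric"):
            fwk.individual_energy(1.0, reg, EnergyFactor(energy_density=1.0),
                                  metric="head_capsule_width")

    def test_out_of_range_computes_with_warning(self):
        reg = MassRegression(metric="total_length", a=1.0, b=1.0,
                             valid_range=(2.0, 5.0))
        with pytest.warns(UserWarning, match="valid range"):
            _, j = fwk.individual_energy(10.0, reg,
                                         EnergyFactor(energy_density=1.0))
        assert j == pytest.approx(10.0)


class TestResolveFactors:
    def test_family_level_fallback_for_species_query(self, tiny_catalog,
                                                     tiny_conversions):
        reg, ef, info = tiny_conversions.resolve_factors(
            tiny_catalog, "baetidae", "larva")
        assert reg.a == 0.003
        assert info["mass_fallback_rank"] == "family"

    def test_order_level_entry_used_when_family_absent(self, tiny_catalog,
                                                       tiny_conversions):
        reg, ef, info = tiny_conversions.resolve_factors(
            tiny_catalog, "chiro", "larva")
        assert reg.a == 0.002  # Diptera order-level entry
        assert info["mass_fallback_rank"] == "order"

    def test_class_default_is_last_resort(self, tiny_catalog,
                                          tiny_conversions):
        reg, ef, info = tiny_conversions.resolve_factors(
            tiny_catalog, "ant", "adult")
        assert reg.a == 0.005
        assert info["mass_fallback_rank"] == "class"
        assert info["default_ind_j"] == 5.0

    def test_unresolvable_taxon_errors_with_name(self, tiny_catalog):
        table = fwk.ConversionTable(pd.DataFrame([
            {"kind": "mass", "class": "Arachnida", "life_stage": "unknown",
             "metric": "total_length", "a": 1.0, "b": 1.0},
            {"kind": "energy", "class": "Arachnida", "life_stage": "unknown",
             "ed": 1.0}]))
        with pytest.raises(EnergeticsError, match="baetidae"):
            table.resolve_factors(tiny_catalog, "baetidae", "larva")

    def _random_table_and_oracle(self, rng, catalog, taxon_id, stage):
        """Random conversion table + exhaustive-scan resolution oracle."""
        path = catalog.rank_path(taxon_id)
        rows = []
        # guaranteed class-level default
        rows.append({"kind": "mass", "class": path["class"],
                     "life_stage": "unknown", "metric": "total_length",
                     "a": rng.uniform(0.5, 2), "b": 1.0})
        stages = ["larva", "adult", "unknown"]
        classes = [path["class"], "OtherClass"]
        for _ in range(rng.integers(2, 8)):
            depth = int(rng.integers(0, len(RANKS)))
            row = {"kind": "mass", "life_stage": stages[rng.integers(3)],
                   "metric": "total_length",
                   "a": rng.uniform(0.5, 2), "b": 1.0}
            cls = classes[rng.integers(2)]
            labels = [cls] + [
                path.get(r, f"X{r}") if rng.random() < 0.7 else f"Z{r}"
                for r in RANKS[1:depth + 1]]
            for r, lab in zip(RANKS, labels):
                row[r] = lab
            rows.append(row)
        table_df = pd.DataFrame(rows)
        # drop duplicate keys so the tie-break cannot differ between routes
        keycols = [*RANKS, "life_stage"]
        for c in keycols:
            if c not in table_df.columns:
                table_df[c] = np.nan
        table_df = table_df.drop_duplicates(subset=keycols)

        def oracle(df):
            best, best_key = None, (-1, -1)
            for _, row in df.iterrows():
                depth = -1
                ok = True
                for i, r in enumerate(RANKS):
                    v = row.get(r)
                    if pd.notna(v):
                        if path.get(r) != v:
                            ok = False
                            break
                        depth = i
                if not ok or depth < 0:
                    continue
                st = row["life_stage"] if pd.notna(row["life_stage"]) \
                    else "unknown"
                if st == stage:
                    pref = 1
                elif st == "unknown":
                    pref = 0
                else:
                    continue
                if (depth, pref) > best_key:
                    best, best_key = row, (depth, pref)
            return best

        return table_df, oracle

    def test_resolution_matches_exhaustive_scan_on_random_tables(
            self, rng, tiny_catalog):
        """Randomized tables: prefix resolution always picks the entry an
        exhaustive longest-prefix scan picks, independent of row order."""
        taxon_id, stage = "baetidae", "larva"
        n_checked = 0
        for _ in range(300):
            df, oracle = self._random_table_and_oracle(rng, tiny_catalog,
                                                       taxon_id, stage)
            edf = df.copy()
            edf["kind"] = "energy"
            edf["ed"] = 1.0
            table = fwk.ConversionTable(pd.concat([df, edf]))
            shuffled = fwk.ConversionTable(
                pd.concat([df, edf]).sample(frac=1, random_state=7))
            reg, _, _ = table.resolve_factors(tiny_catalog, taxon_id, stage)
            reg2, _, _ = shuffled.resolve_factors(tiny_catalog, taxon_id,
                                                  stage)
            expect = oracle(df)
            assert reg.a == pytest.approx(float(expect["a"]))
            assert reg2.a == pytest.approx(reg.a)  # row-order invariance
            n_checked += 1
        assert n_checked == 300


class TestAnnotateEnergy:
    def test_density_arithmetic(self, tiny_catalog, tiny_conversions):
        samples = pd.DataFrame([{"sample_id": "s", "section": "LE",
                                 "season": "summer", "period": "Pre",
                                 "habitat": "mainstem", "gear": "drift",
                                 "effort": 2.0, "effort_unit": "m3"}])
        obs = pd.DataFrame([
            {"sample_id": "s", "taxon_id": "baetidae", "count": 2,
             "metric": "total_length", "lengths_mm": "4.0;2.0"}])
        reg, ef, _ = tiny_conversions.resolve_factors(tiny_catalog,
                                                      "baetidae", "larva")
        expect = sum(fwk.individual_energy(L, reg, ef)[1] for L in (4.0, 2.0))
        ann = fwk.annotate_energy(fwk.SampleSet(samples, obs), tiny_catalog,
                                  tiny_conversions)
        assert ann.observations["energy_j"].iloc[0] == pytest.approx(expect)
        assert fwk.energy_density(ann, "s") == pytest.approx(expect / 2.0)

    def test_empty_sample_zero_density(self, tiny_catalog, tiny_conversions):
        samples = pd.DataFrame([{"sample_id": "s", "section": "LE",
                                 "season": "summer", "period": "Pre",
                                 "habitat": "mainstem", "gear": "drift",
                                 "effort": 2.0, "effort_unit": "m3"}])
        ss = fwk.SampleSet(samples, pd.DataFrame(
            columns=["sample_id", "fish_id", "taxon_id", "count", "metric",
                     "lengths_mm"]))
        ann = fwk.annotate_energy(ss, tiny_catalog, tiny_conversions)
        assert fwk.energy_density(ann, "s") == 0.0

    def test_unmeasured_individuals_use_conspecific_mean(self, tiny_catalog,
                                                         tiny_conversions):
        samples = pd.DataFrame([{"sample_id": "s", "section": "LE",
                                 "season": "summer", "period": "Pre",
                                 "habitat": "mainstem", "gear": "drift",
                                 "effort": 1.0, "effort_unit": "m3"}])
        obs = pd.DataFrame([
            {"sample_id": "s", "taxon_id": "baetidae", "count": 4,
             "metric": "total_length", "lengths_mm": "4.0;2.0"}])
        reg, ef, _ = tiny_conversions.resolve_factors(tiny_catalog,
                                                      "baetidae", "larva")
        measured = [fwk.individual_energy(L, reg, ef)[1] for L in (4.0, 2.0)]
        expect = sum(measured) + 2 * np.mean(measured)
        ann = fwk.annotate_energy(fwk.SampleSet(samples, obs), tiny_catalog,
                                  tiny_conversions)
        assert ann.observations["energy_j"].iloc[0] == pytest.approx(expect)

    def test_total_matches_per_individual_brute_force(self, rng):
        """Module totals equal a brute-force per-individual summation over
        a simulated sample set (conservation of joules)."""
        params = fwk.SimParams(samples_per_cell=2, n_aquatic=6,
                               n_terrestrial=2, seasons=("summer",),
                               sections=("LE",), periods=("Pre",))
        cat, ss, _ = fwk.simulate_community(params, seed=5)
        table = fwk.make_conversion_table(cat, seed=0)
        ann = fwk.annotate_energy(ss, cat, table)
        from foodwebkit.data_model import parse_lengths
        brute = 0.0
        for _, row in ss.observations.iterrows():
            reg, ef, _ = table.resolve_factors(cat, row["taxon_id"])
            lens = parse_lengths(row["lengths_mm"])
            js = [fwk.individual_energy(L, reg, ef)[1] for L in lens]
            brute += sum(js)
            if row["count"] > len(lens) and js:
                brute += (row["count"] - len(lens)) * np.mean(js)
        assert ann.observations["energy_j"].sum() == pytest.approx(
            brute, rel=1e-6)
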