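import numpy as np
import pandas as pd
import pytest

from foodwebkit import (ConversionTable, SampleSet, TaxonCatalog)


@pytest.fixture
def tiny_catalog() -> TaxonCatalog:
    """Four taxa: two aquatic families, one terrestrial family, and one
    aquatic taxon identified only to Order (digested fragments)."""
    return TaxonCatalog(pd.DataFrame([
        {"taxon_id": "baetidae", "class": "Insecta", "order": "Ephemeroptera",
         "family": "Baetidae", "genus": None, "species": None,
         "origin": "aquatic", "life_stage": "larva"},
        {"taxon_id": "chiro", "class": "Insecta", "order": "Diptera",
         "family": "Chironomidae", "genus": None, "species": None,
         "origin": "aquatic", "life_stage": "larva"},
        {"taxon_id": "ant", "class": "Insecta", "order": "Hymenoptera",
         "family": "Formicidae", "genus": None, "species": None,
         "origin": "terrestrial", "life_stage": "adult"},
        {"taxon_id": "dipt_unid", "class": "Insecta", "order": "Diptera",
         "family": None, "genus": None, "species": None,
         "origin": "aquatic", "life_stage": "unknown"},
    ]))


@pytest.fixture
def tiny_sampleset() -> SampleSet:
    samples = pd.DataFrame([
        {"sample_id": "dr1", "section": "LE", "season": "summer",
         "period": "Pre", "habitat": "mainstem", "gear": "drift",
         "effort": 2.0, "effort_unit": "m3"},
        {"sample_id": "dr2", "section": "LE", "season": "summer",
         "period": "2013", "habitat": "mainstem", "gear": "drift",
         "effort": 4.0, "effort_unit": "m3"},
        {"sample_id": "be1", "section": "Estuary", "season": "spring",
         "period": "Pre", "habitat": "estuary", "gear": "benthic",
         "effort": 0.0225, "effort_unit": "m2"},
    ])
    obs = pd.DataFrame([
        {"sample_id": "dr1", "fish_id": None, "taxon_id": "baetidae",
         "count": 6, "metric": "total_length", "lengths_mm": "4.0;5.0"},
        {"sample_id": "dr1", "fish_id": None, "taxon_id": "ant",
         "count": 2, "metric": "total_length", "lengths_mm": "6.0"},
        {"sample_id": "dr2", "fish_id": None, "taxon_id": "chiro",
         "count": 8, "metric": "total_length", "lengths_mm": "3.0;3.0;3.0"},
        {"sample_id": "be1", "fish_id": None, "taxon_id": "dipt_unid",
         "count": 3, "metric": "total_length", "lengths_mm": "2.0"},
    ])
    return SampleSet(samples, obs)


@pytest.fixture
def tiny_conversions() -> ConversionTable:
    return ConversionTable(pd.DataFrame([
        {"kind": "mass", "class": "Insecta", "order": "Ephemeroptera",
         "family": "Baetidae", "life_stage": "larva",
         "metric": "total_length", "a": 0.003, "b": 2.7},
        {"kind": "mass", "class": "Insecta", "order": "Diptera",
         "life_stage": "unknown", "metric": "total_length",
         "a": 0.002, "b": 2.5},
        {"kind": "mass", "class": "Insecta", "life_stage": "unknown",
         "metric": "total_length", "a": 0.005, "b": 2.6},
        {"kind": "energy", "class": "Insecta", "order": "Ephemeroptera",
         "family": "Baetidae", "life_stage": "larva", "ed": 24.0, "pdm": 0.2},
        {"kind": "energy", "class": "Insecta", "order": "Diptera",
         "life_stage": "unknown", "ed": 20.0, "pdm": 0.2},
        {"kind": "energy", "class": "Insecta", "life_stage": "unknown",
         "ed": 22.0, "pdm": 0.25, "default_ind_j": 5.0},
    ]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
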