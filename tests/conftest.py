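"""Shared fixtures: a small synthetic dataset and the 20-dataset study."""

from __future__ import annotations

import numpy as np
import pytest

from teexon import hurdle, quantify, variability
from teexon.class_stats import class_summary_table
from teexon.simulate import (GeneratorConfig, REFERENCE_SAMPLE,
                             simulate_dataset)

SMALL_CONFIG = GeneratorConfig(seed=11, n_genes=60, n_c3=25, n_c4=120,
                               n_fictional=80)

N_STUDY_DATASETS = 20


def quantify_dataset(ds):
    """Quantify every sample of a simulated dataset."""
    return [quantify.quantify_sample(
        ds.annotation, sample_id=c, counts=ds.counts[c],
        total_filtered_reads=int(ds.library_sizes[c]))
        for c in ds.counts.columns]


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_samples(small_dataset):
    return quantify_dataset(small_dataset)


@pytest.fixture(scope="session")
def study(request):
    """Twenty default-condition datasets, analysed end to end.

    For each dataset: the reference (uncontrasted) sample's two-step
    fit, the per-sample class summary table, and the cross-sample
    median/CV Kendall correlation of the TE exons.
    """
    results = []
    for seed in range(N_STUDY_DATASETS):
        ds = simulate_dataset(GeneratorConfig(seed=seed))
        samples = quantify_dataset(ds)
        ref = next(s for s in samples if s.sample_id == REFERENCE_SAMPLE)
        fit = hurdle.two_step_fit(ref, ds.annotation)
        class_table = class_summary_table(samples, ds.annotation)
        matrix = variability.build_expression_matrix(
            samples, ds.annotation, ds.samples).subset_classes("C3", "C4")
        disp = variability.dispersion_summary(matrix, min_samples=13)
        tau, tau_p = variability.kendall_tau(disp["m"], disp["v"])
        results.append({
            "truth": ds.truth,
            "fit": fit,
            "class_table": class_table,
            "tau": tau,
        })
    return results
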