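"""Shared synthetic-cohort fixtures.

The expensive cohort (n=2000, 50 CpGs, models trained at a 250 kb window) is
session-scoped and shared by the training-recovery, heritability-bound and
summary-statistic tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from cismwas import (
    SimulationConfig,
    fit_penalized,
    simulate_genotypes,
    simulate_gwas_sumstats,
    simulate_methylation,
    split_samples,
    extract_window,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Light cohort for unit-level checks (n=400, 10 CpGs)."""
    cfg = SimulationConfig(n_samples=400, n_cpgs=10, seed=7)
    panel = simulate_genotypes(cfg)
    meth, truth = simulate_methylation(panel, cfg)
    return {"config": cfg, "panel": panel, "meth": meth, "truth": truth}


@pytest.fixture(scope="session")
def big_cohort():
    """Main study cohort: n=2000, 50 CpGs, cis-h2 0.5, 5 phenotype drivers.

    Models are trained with elastic net (mixing 0.5) at a 250 kb window on the
    50% training split; the 20% split is the internal test set. GWAS summary
    statistics and dosage covariances derive from all samples, which is what
    makes the summary-statistic association exactly comparable with an
    individual-level regression oracle.
    """
    cfg = SimulationConfig(
        n_samples=2000, n_cpgs=50, h2_cis=0.5, prop_heritable_cpgs=0.8,
        phenotype_causal_cpgs=5, phenotype_h2=0.1, seed=11,
    )
    panel = simulate_genotypes(cfg)
    meth, truth = simulate_methylation(panel, cfg)
    sumstats, phenotype = simulate_gwas_sumstats(panel, meth, truth, cfg)
    scheme = split_samples(panel.samples, (0.5, 0.2, 0.3), 11)

    models = {}
    window_idx = {}
    for i, cpg in enumerate(truth.heritable_cpgs):
        info = meth.cpgs[meth.cpgs["cpg_id"] == cpg].iloc[0]
        idx = extract_window(panel, info["chrom"], int(info["pos"]), 250_000)
        model = fit_penalized(
            meth.cpg_vector(cpg)[scheme.train],
            panel.dosages[np.ix_(scheme.train, idx)],
            alpha=0.5,
            seed=100 + i,
            variants=panel.variants.iloc[idx].reset_index(drop=True),
            cpg_id=cpg,
            window=250_000,
        )
        if model is not None:
            models[cpg] = model
            window_idx[cpg] = idx
    return {
        "config": cfg,
        "panel": panel,
        "meth": meth,
        "truth": truth,
        "sumstats": sumstats,
        "phenotype": phenotype,
        "scheme": scheme,
        "models": models,
        "window_idx": window_idx,
    }
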