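"""Self-contained validation experiments for the MALDR pipeline.

Each function builds its inputs from the synthetic generator (or a direct
NB sampler), runs the relevant pipeline stages, and returns measured
operating characteristics: detection power and false-pass rate of the
full pre-filter + MALDR chain, type-I error of the NB quasi-likelihood
test, and the outlier-donor (ID1-like) caveat scenario.  They are used by
the test suite and by the acceptance script.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
import pandas as pd

from maldr_age import maldr as md
from maldr_age import prefilter as pf
from maldr_age import synthetic_data as sd
from maldr_age.params import MaldrParameters


def parameter_recovery(seed: int, n_genes: int = 200, n_injected: int = 50,
                       ratio: float = 1.5,
                       nb_dispersion: float = 0.1) -> Dict[str, float]:
    """Power / false-pass of prefilter + MALDR on an injected cohort.

    ``n_injected`` genes (half up, half down) carry a monotone per-step
    fold change of ``ratio`` across Young -> Middle -> Old; the remaining
    genes are null.  All other generator settings are defaults (54
    samples, 18 per age group, donor effect sigma 0.3).  A gene counts as
    recovered when it survives the Young-vs-Old FDR pre-filter *and*
    passes the monotone-ratio filter with the matching direction.
    """
    genes = sd.generate_gene_models(
        sd.SyntheticGenomeSpec(n_genes=n_genes), seed=seed)
    samples = sd.simulate_cohort(sd.CohortSpec(seed=seed))
    n_up = n_injected // 2
    inj_up = [g.gene_id for g in genes[:n_up]]
    inj_dn = [g.gene_id for g in genes[n_up:n_injected]]
    effects = (
        [sd.EffectSpec(g, "monotone_up", ratio=ratio) for g in inj_up]
        + [sd.EffectSpec(g, "monotone_down", ratio=ratio) for g in inj_dn])
    counts = sd.simulate_counts(genes, samples, effects,
                                nb_dispersion=nb_dispersion, seed=seed)
    depths = sd.simulate_depth_profiles(genes, samples, effects, seed=seed)
    res = pf.run_prefilter(counts, samples, "age_group",
                           levels=("Young", "Old"))
    selected = pf.select_prefiltered_genes(res)
    gap_sites = {g.gene_id: g.annotated_gap_sites() for g in genes}
    mres = md.run_maldr(selected, depths, gap_sites, samples)
    passing = set(mres.index[mres["passes"]])
    injected = set(inj_up) | set(inj_dn)
    n_null = n_genes - n_injected
    return {
        "power": len(passing & injected) / n_injected,
        "null_false_pass_rate": len(passing - injected) / n_null,
        "n_prefiltered": len(selected),
        "n_injected_prefiltered": len(selected & injected),
        "n_passing": len(passing),
    }


def type_one_error(seed: int, n_features: int = 2000,
                   n_per_group: int = 18, phi: float = 0.1,
                   alpha: float = 0.05,
                   mean_range=(100.0, 1000.0)) -> Dict[str, float]:
    """Empirical type-I error of the NB QL F-test on null features.

    Counts are NB(mean, ``phi``) with per-sample library factors and no
    group difference; dispersions are estimated by the standard pipeline
    (method of moments + trend shrinkage) before testing.
    """
    rng = np.random.default_rng([int(seed), 61])
    n = 2 * n_per_group
    lib = rng.uniform(0.8, 1.2, n)
    mu = np.outer(rng.uniform(*mean_range, n_features), lib)
    y = rng.poisson(rng.gamma(1.0 / phi, phi * mu)) if phi > 0 \
        else rng.poisson(mu)
    counts = pd.DataFrame(y, index=[f"f{i}" for i in range(n_features)],
                          columns=[f"s{j}" for j in range(n)])
    design = pd.Series(["A"] * n_per_group + ["B"] * n_per_group,
                       index=counts.columns)
    disp = pf.estimate_dispersions(counts, design)
    res = pf.nb_group_test(counts, design, disp)
    return {
        "rejection_rate": float((res["p_value"] < alpha).mean()),
        "alpha": alpha,
        "n_features": int(len(res)),
    }


def outlier_donor_scenario(seed: int, outlier_fold: float = 10.0,
                           n_genes: int = 30) -> Dict[str, object]:
    """The ID1-like caveat: 3 of 27 donors strongly over-express one gene.

    Two Young donors and one Middle donor carry a ``outlier_fold``-times
    elevated expression of one gene; the population carries no age trend.
    Returns the MALDR outcome for that gene, which passes the filter in
    the decreasing direction because the outliers inflate the Young and
    Middle group means.
    """
    genes = sd.generate_gene_models(
        sd.SyntheticGenomeSpec(n_genes=n_genes), seed=seed)
    samples = sd.simulate_cohort(sd.CohortSpec(seed=seed))
    young = samples.loc[samples["age_group"] == "Young", "donor"].unique()
    middle = samples.loc[samples["age_group"] == "Middle", "donor"].unique()
    target = genes[0].gene_id
    effects = [sd.EffectSpec(target, "outlier_donors",
                             outlier_donor_ids=(young[0], young[1],
                                                middle[0]),
                             outlier_fold=outlier_fold)]
    depths = sd.simulate_depth_profiles(genes, samples, effects, seed=seed)
    gap_sites = {g.gene_id: g.annotated_gap_sites() for g in genes}
    res = md.run_maldr([target], depths, gap_sites, samples)
    row = res.loc[target]
    return {"gene_id": target, "passes": bool(row["passes"]),
            "direction": str(row["direction"]),
            "monotone_fraction": float(row["monotone_fraction"])}
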