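"""Named study conditions used by the validation suite and worked examples.

Each function returns a :class:`~fcmega.cohort.CohortConfig` describing a
synthetic multi-site study:

``null_calibration``
    12 sites x 40 subjects, 42 parcels, 150 timepoints, no group-linked
    effects but full nuisance structure (site offsets, site case-mix
    heterogeneity, motion noise).  Used to check that the group test
    holds its nominal type-I error and that omitting the site random
    intercept inflates it.

``smn_hypoconnectivity``
    A consortium-scale cohort (16 sites x 68 subjects ~ 1,050 analysed)
    with reduced within-SMN correlation sized so the transformed-scale
    group effect lands near d ~ 0.26, plus a smaller within-SN
    reduction.  The within-network effect sizes are chosen so that the
    network-level FC comparison flags SMN most strongly and the
    segregation comparison flags SMN only.

``smn_age_decline``
    Within-SMN correlation declines with age in cases only, producing a
    group-specific negative age slope of SMN segregation.

``multisite_concordance``
    15 sites with hypoconnectivity spread over several sensory/attention
    networks; used to compare one-stage (mega) and two-stage (meta)
    estimates feature by feature.
"""

from __future__ import annotations

from .cohort import CohortConfig


def null_calibration(seed: int = 0) -> CohortConfig:
    return CohortConfig(n_sites=12, per_site_n=40, n_parcels=42,
                        n_timepoints=150, site_sd=0.05, seed=seed)


def smn_hypoconnectivity(seed: int = 0) -> CohortConfig:
    return CohortConfig(n_sites=16, per_site_n=68, n_parcels=42,
                        n_timepoints=150, site_sd=0.05,
                        group_effect={"SMN": -0.012, "SN": -0.004},
                        seed=seed)


def smn_age_decline(seed: int = 0) -> CohortConfig:
    return CohortConfig(n_sites=12, per_site_n=40, n_parcels=42,
                        n_timepoints=150, site_sd=0.05,
                        age_group_slope={"SMN": -0.003}, seed=seed)


def multisite_concordance(seed: int = 0) -> CohortConfig:
    return CohortConfig(n_sites=15, per_site_n=60, n_parcels=42,
                        n_timepoints=150, site_sd=0.05,
                        group_effect={"SMN": -0.012, "SN": -0.006,
                                      "DAN": -0.004, "VN": -0.004},
                        seed=seed)
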