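"""Synthetic multi-site resting-state cohort generator.

Emulates the statistical structure a multi-site case/control connectome
study assumes: each subject's parcel time series are drawn from a
multivariate normal whose correlation matrix has a block structure over
seven canonical cortical networks (VN, SMN, DAN, SN, LN, FPN, DMN), with

* within-network correlation ``base_within_r`` and between-network
  correlation ``base_between_r``,
* additive group effects on designated within-network blocks for cases
  (hypo-/hyperconnectivity),
* a per-site additive offset on all latent correlations (scanner/protocol
  heterogeneity),
* optional severity, medication and age-by-group perturbations, and
* white measurement noise whose variance grows with the subject's mean
  framewise displacement (motion attenuates observed correlations).

Perturbed correlation matrices are clipped to (-1, 1) and, if indefinite,
repaired to the nearest positive semi-definite correlation matrix before
sampling, so the generating distribution is always valid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.correlation_tools import corr_nearest

NETWORKS: tuple[str, ...] = ("VN", "SMN", "DAN", "SN", "LN", "FPN", "DMN")

SEVERITY_LEVELS: tuple[str, ...] = (
    "remitted", "mild", "moderate", "severe", "very_severe",
)

# Marginal category frequencies typical of a large clinical consortium
# sample; "unknown" models sites that did not report the item.
SEVERITY_PROBS: dict[str, float] = {
    "remitted": 0.233, "mild": 0.168, "moderate": 0.332,
    "severe": 0.167, "very_severe": 0.064, "unknown": 0.036,
}
MEDICATION_PROBS: dict[str, float] = {"yes": 0.632, "no": 0.363, "unknown": 0.005}

_R_CLIP = 0.999


@dataclass(frozen=True)
class NetworkAtlas:
    """Assignment of each parcel to exactly one of the seven networks."""

    parcel_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.parcel_ids) != len(self.labels):
            raise ValueError("parcel_ids and labels must have equal length")
        if len(set(self.parcel_ids)) != len(self.parcel_ids):
            raise ValueError("duplicate parcel ids in atlas")
        bad = set(self.labels) - set(NETWORKS)
        if bad:
            raise ValueError(f"unknown network labels: {sorted(bad)}")
        missing = set(NETWORKS) - set(self.labels)
        if missing:
            raise ValueError(f"empty networks: {sorted(missing)}")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    @property
    def networks(self) -> tuple[str, ...]:
        return NETWORKS

    def indices(self, network: str) -> np.ndarray:
        """Column indices of the parcels belonging to *network*."""
        if network not in NETWORKS:
            raise KeyError(f"unknown network {network!r}")
        cache = self.__dict__.get("_indices_cache")
        if cache is None:
            cache = {}
            object.__setattr__(self, "_indices_cache", cache)
        if network not in cache:
            cache[network] = np.array(
                [i for i, l in enumerate(self.labels) if l == network])
        return cache[network]

    def network_of(self, parcel_id: str) -> str:
        try:
            return self.labels[self.parcel_ids.index(parcel_id)]
        except ValueError:
            raise KeyError(f"parcel {parcel_id!r} not in atlas") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parcel_id": self.parcel_ids, "network": self.labels})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NetworkAtlas":
        return cls(tuple(df["parcel_id"].astype(str)), tuple(df["network"].astype(str)))


def default_atlas(n_parcels: int = 42) -> NetworkAtlas:
    """Partition ``n_parcels`` into seven contiguous network blocks.

    Parcels are distributed as evenly as possible (e.g. 42 -> 6 per
    network, 400 -> blocks of 57/58).
    """
    if n_parcels < len(NETWORKS) * 2:
        raise ValueError("need at least two parcels per network")
    base, extra = divmod(n_parcels, len(NETWORKS))
    sizes = [base + (1 if i < extra else 0) for i in range(len(NETWORKS))]
    labels: list[str] = []
    for net, size in zip(NETWORKS, sizes):
        labels.extend([net] * size)
    ids = tuple(f"p{i:04d}" for i in range(n_parcels))
    return NetworkAtlas(ids, tuple(labels))


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject metadata row of the participants table."""

    subject_id: str
    site_id: str
    group: str                 # "MDD" or "HC"
    age: float                 # years
    sex: str                   # "F" or "M"
    mean_fd: float             # mm, >= 0
    medication: str | None = None   # "yes"/"no"/"unknown", cases only
    severity: str | None = None     # severity category or "unknown", cases only

    def __post_init__(self) -> None:
        if self.group not in ("MDD", "HC"):
            raise ValueError(f"group must be MDD or HC, got {self.group!r}")
        if self.group == "HC" and (self.medication is not None or self.severity is not None):
            raise ValueError("controls carry no medication/severity status")


@dataclass(frozen=True)
class ParcelTimeSeries:
    """One subject's T x P parcel signal matrix."""

    subject_id: str
    values: np.ndarray
    parcel_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D (timepoints x parcels) array")
        if v.shape[1] != len(self.parcel_ids):
            raise ValueError("column count does not match parcel_ids")
        object.__setattr__(self, "values", v)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters of a synthetic multi-site cohort.

    Correlation-scale effects (``group_effect``, ``severity_effect``,
    ``medication_effect``, ``age_group_slope``) are mappings from network
    label to an additive change of the within-network latent correlation;
    unlisted networks are untouched.  ``age_group_slope`` is per year of
    age, centred at the midpoint of ``age_range``, and applies to cases
    only, which produces a group-specific age trend in within-network
    connectivity and segregation.
    """

    n_sites: int = 12
    per_site_n: int | Sequence[int] = 40
    case_fraction: float = 0.56
    case_fraction_sd: float = 0.15
    n_parcels: int = 42
    n_timepoints: int = 150
    base_within_r: float = 0.35
    base_between_r: float = 0.08
    group_effect: Mapping[str, float] = field(default_factory=dict)
    group_effect_site_sd: float = 0.0  # relative per-site scaling of group_effect
    site_sd: float = 0.02
    motion_coupling: float = 0.5
    age_range: tuple[float, float] = (18.0, 65.0)
    severity_effect: Mapping[str, float] = field(default_factory=dict)
    medication_effect: Mapping[str, float] = field(default_factory=dict)
    age_group_slope: Mapping[str, float] = field(default_factory=dict)
    female_fraction: float = 0.59
    high_motion_frac: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        if self.n_parcels < 14:
            raise ValueError("need at least two parcels per network")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        for name in ("base_within_r", "base_between_r"):
            r = getattr(self, name)
            if not -1 < r < 1:
                raise ValueError(f"{name} must lie in (-1, 1)")
        if min(self.site_sd, self.motion_coupling, self.case_fraction_sd,
               self.group_effect_site_sd) < 0:
            raise ValueError("site_sd, motion_coupling, case_fraction_sd and "
                             "group_effect_site_sd must be >= 0")
        for eff in (self.group_effect, self.severity_effect,
                    self.medication_effect, self.age_group_slope):
            bad = set(eff) - set(NETWORKS)
            if bad:
                raise ValueError(f"effects reference unknown networks: {sorted(bad)}")

    def site_sizes(self) -> list[int]:
        if isinstance(self.per_site_n, int):
            return [self.per_site_n] * self.n_sites
        sizes = list(self.per_site_n)
        if len(sizes) != self.n_sites:
            raise ValueError("per_site_n list length must equal n_sites")
        return sizes


@dataclass
class Cohort:
    """Generated cohort: metadata, per-subject series, atlas and ground truth.

    ``truth`` holds, per subject and network, the expected Fisher-z
    within-network connectivity implied by that subject's generating
    correlation matrix after motion attenuation — the quantity downstream
    recovery tests compare model estimates against.
    """

    records: list[SubjectRecord]
    series: list[ParcelTimeSeries]
    atlas: NetworkAtlas
    truth: pd.DataFrame
    site_offsets: dict[str, float]

    def participants(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Participants table (one row per subject) from record objects."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def frame_to_records(df: pd.DataFrame) -> list[SubjectRecord]:
    recs = []
    for row in df.itertuples(index=False):
        med = getattr(row, "medication", None)
        sev = getattr(row, "severity", None)
        recs.append(SubjectRecord(
            subject_id=str(row.subject_id), site_id=str(row.site_id),
            group=str(row.group), age=float(row.age), sex=str(row.sex),
            mean_fd=float(row.mean_fd),
            medication=None if med is None or (isinstance(med, float) and np.isnan(med)) else str(med),
            severity=None if sev is None or (isinstance(sev, float) and np.isnan(sev)) else str(sev),
        ))
    return recs


def _severity_multiplier(severity: str | None) -> float:
    # Monotone ramp over ordered categories; unknown carries no effect.
    if severity in (None, "unknown"):
        return 0.0
    return SEVERITY_LEVELS.index(severity) / (len(SEVERITY_LEVELS) - 1)


def _block_base(atlas: NetworkAtlas, within: float, between: float) -> np.ndarray:
    labels = np.asarray(atlas.labels)
    same = labels[:, None] == labels[None, :]
    corr = np.where(same, within, between).astype(float)
    np.fill_diagonal(corr, 1.0)
    return corr


def subject_correlation(config: CohortConfig, atlas: NetworkAtlas,
                        record: SubjectRecord, site_offset: float,
                        group_effect_scale: float = 1.0) -> np.ndarray:
    """Latent correlation matrix for one subject, PSD-repaired if needed.

    ``group_effect_scale`` multiplies the per-network group effects; the
    generator uses it to model between-site heterogeneity of the case
    effect (``group_effect_site_sd``).
    """
    corr = _block_base(atlas, config.base_within_r, config.base_between_r)
    off = ~np.eye(atlas.n_parcels, dtype=bool)
    corr[off] += site_offset

    if record.group == "MDD":
        age_mid = 0.5 * (config.age_range[0] + config.age_range[1])
        sev_mult = _severity_multiplier(record.severity)
        for net in NETWORKS:
            delta = group_effect_scale * config.group_effect.get(net, 0.0)
            delta += sev_mult * config.severity_effect.get(net, 0.0)
            if record.medication == "yes":
                delta += config.medication_effect.get(net, 0.0)
            delta += (record.age - age_mid) * config.age_group_slope.get(net, 0.0)
            if delta != 0.0:
                idx = atlas.indices(net)
                corr[np.ix_(idx, idx)] += delta
                np.fill_diagonal(corr, 1.0)

    np.clip(corr, -_R_CLIP, _R_CLIP, out=corr)
    np.fill_diagonal(corr, 1.0)
    return _ensure_psd(corr, record)


#: largest entrywise shift the PSD repair may apply before the requested
#: parameters are considered unrealisable as a correlation structure
_MAX_REPAIR_SHIFT = 0.15


def _ensure_psd(corr: np.ndarray, record: SubjectRecord) -> np.ndarray:
    eig_min = np.linalg.eigvalsh(corr)[0]
    if eig_min > 1e-10:
        return corr
    import warnings

    from statsmodels.stats.correlation_tools import corr_clipped
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        repaired = corr_nearest(corr, threshold=1e-7, n_fact=200)
        if np.linalg.eigvalsh(repaired)[0] < 1e-10:
            # Higham alternating projections stalled; fall back to a single
            # eigenvalue clip + renormalisation, which always lands PSD.
            repaired = corr_clipped(corr, threshold=1e-7)
    shift = float(np.max(np.abs(repaired - corr)))
    if shift > _MAX_REPAIR_SHIFT or np.linalg.eigvalsh(repaired)[0] < -1e-8:
        raise ValueError(
            f"correlation matrix for subject {record.subject_id} "
            f"({record.group}, site {record.site_id}) cannot be repaired to a "
            f"positive semi-definite matrix near the requested one (nearest "
            f"valid matrix deviates by {shift:.3f}); reduce the injected "
            "group/site/severity effects or the base correlations"
        )
    return repaired


_FD_SHAPE, _FD_SCALE, _FD_SHIFT = 3.0, 0.06, 0.03
_FD_CAP: float | None = None


def _draw_mean_fd(rng: np.random.Generator, config: CohortConfig) -> float:
    """Right-skewed motion summary; a configurable tail exceeds 0.55 mm."""
    from scipy.special import gammainc, gammaincinv

    global _FD_CAP
    if rng.uniform() < config.high_motion_frac:
        return 0.56 + rng.gamma(2.0, 0.15)
    # shifted gamma truncated below the QC threshold via inverse-CDF
    if _FD_CAP is None:
        _FD_CAP = float(gammainc(_FD_SHAPE, (0.52 - _FD_SHIFT) / _FD_SCALE))
    q = rng.uniform() * _FD_CAP
    return _FD_SHIFT + _FD_SCALE * float(gammaincinv(_FD_SHAPE, q))


_SEVERITY_CUTS: np.ndarray | None = None


def _draw_severity(rng: np.random.Generator) -> str:
    # Latent-score thresholding: one standard-normal draw cut at the
    # quantiles of the ordered category frequencies.
    global _SEVERITY_CUTS
    if rng.uniform() < SEVERITY_PROBS["unknown"]:
        return "unknown"
    if _SEVERITY_CUTS is None:
        from scipy.stats import norm

        probs = np.array([SEVERITY_PROBS[s] for s in SEVERITY_LEVELS])
        probs = probs / probs.sum()
        _SEVERITY_CUTS = norm.ppf(np.cumsum(probs)[:-1])
    z = rng.standard_normal()
    return SEVERITY_LEVELS[int(np.searchsorted(_SEVERITY_CUTS, z))]


def _draw_medication(rng: np.random.Generator) -> str:
    u = rng.uniform()
    if u < MEDICATION_PROBS["yes"]:
        return "yes"
    if u < MEDICATION_PROBS["yes"] + MEDICATION_PROBS["no"]:
        return "no"
    return "unknown"


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full multi-site cohort (metadata + parcel time series).

    Deterministic for a fixed ``config.seed``: the same configuration
    yields bit-identical metadata and series.
    """
    rng = np.random.default_rng(config.seed)
    atlas = default_atlas(config.n_parcels)
    sizes = config.site_sizes()
    site_ids = [f"site{k:02d}" for k in range(config.n_sites)]
    site_offsets = {s: (config.site_sd * rng.standard_normal() if config.site_sd > 0 else 0.0)
                    for s in site_ids}
    effect_scales = {s: (1.0 + config.group_effect_site_sd * rng.standard_normal()
                         if config.group_effect_site_sd > 0 else 1.0)
                     for s in site_ids}

    records: list[SubjectRecord] = []
    series: list[ParcelTimeSeries] = []
    truth_rows: list[dict] = []
    labels = np.asarray(atlas.labels)
    within_flat = {}
    for net in NETWORKS:
        mask = np.triu(np.outer(labels == net, labels == net), 1)
        within_flat[net] = np.nonzero(mask.ravel())[0]

    sub = 0
    _corr_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
    for site, n_site in zip(site_ids, sizes):
        # Sites differ systematically in their case mix (patient-heavy
        # clinics vs control-heavy centres): each site gets its own case
        # fraction around case_fraction, then subjects draw Bernoulli.
        p_site = float(np.clip(
            config.case_fraction + config.case_fraction_sd * rng.standard_normal(),
            0.05, 0.95))
        for i in range(n_site):
            group = "MDD" if rng.uniform() < p_site else "HC"
            age = float(rng.uniform(*config.age_range))
            sex = "F" if rng.uniform() < config.female_fraction else "M"
            mean_fd = _draw_mean_fd(rng, config)
            severity = _draw_severity(rng) if group == "MDD" else None
            medication = _draw_medication(rng) if group == "MDD" else None
            rec = SubjectRecord(
                subject_id=f"sub{sub:05d}", site_id=site, group=group,
                age=age, sex=sex, mean_fd=mean_fd,
                medication=medication, severity=severity,
            )
            # subjects with identical effect determinants share corr + chol
            age_key = round(age, 9) if (group == "MDD" and config.age_group_slope) else None
            key = (site, group, _severity_multiplier(severity) if group == "MDD" else 0.0,
                   medication == "yes", age_key)
            cached = _corr_cache.get(key)
            if cached is None:
                corr = subject_correlation(config, atlas, rec, site_offsets[site],
                                           effect_scales[site])
                L = np.linalg.cholesky(corr + 1e-10 * np.eye(atlas.n_parcels))
                _corr_cache[key] = (corr, L)
            else:
                corr, L = cached
            signal = rng.standard_normal((config.n_timepoints, atlas.n_parcels)) @ L.T
            noise_var = config.motion_coupling * mean_fd
            if noise_var > 0:
                signal = signal + np.sqrt(noise_var) * rng.standard_normal(signal.shape)
            records.append(rec)
            series.append(ParcelTimeSeries(rec.subject_id, signal, atlas.parcel_ids))

            # Expected within-network Fisher z after motion attenuation:
            # adding white noise of variance v to unit-variance signals
            # multiplies every off-diagonal correlation by 1/(1+v).
            atten = 1.0 / (1.0 + noise_var)
            flat = corr.ravel()
            row = {"subject_id": rec.subject_id}
            for net in NETWORKS:
                vals = flat[within_flat[net]] * atten
                row[f"true_z_{net}"] = float(np.arctanh(vals).mean())
            truth_rows.append(row)
            sub += 1

    return Cohort(records, series, atlas, pd.DataFrame(truth_rows), site_offsets)


def null_config(config: CohortConfig) -> CohortConfig:
    """Copy of *config* with every group-linked effect forced to zero."""
    return dataclasses.replace(
        config, group_effect={}, severity_effect={},
        medication_effect={}, age_group_slope={},
    )


def generate_null_cohort(config: CohortConfig) -> Cohort:
    """Cohort in which case/control labels are exchangeable by construction.

    Site offsets and motion noise are retained, so the null preserves the
    nuisance structure (useful for type-I-error calibration of the group
    test) while group, severity and medication carry no signal.
    """
    return generate_cohort(null_config(config))
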