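"""Synthetic PET phantoms and simulated survival cohorts.

Two generators make the whole pipeline exercisable without patient data:

* :func:`generate_phantom` builds an FDG-avid ellipsoidal tumour on a uniform
  background, with spatially correlated intra-tumour heterogeneity (Gaussian
  random field) and optional white noise, plus its ground-truth mask.
* :func:`generate_cohort` draws patient covariates and PET metrics from
  documented distributions and simulates overall survival from a proportional
  hazards model whose default weights are the published prognostic-model
  coefficients, with independent exponential censoring and an administrative
  cutoff.

Every output is a pure function of (spec/config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import GeometryError, ValidationError
from .io import BinaryMask, PETVolume

#: Published prognostic-model coefficients (log hazard ratios) used as the
#: default generating truth and as the frozen score weights downstream.
PUBLISHED_COEFFICIENTS: dict[str, float] = {
    "stage_group": 0.397,
    "treatment": -1.094,
    "age": 0.024,
    "log_hist_energy": -1.320,
    "log_tlg": 1.748,
    "hist_kurtosis": 0.198,
}

#: The 19 candidate variables of the full prognostic Cox model: three clinical
#: covariates plus the 16 PET metrics, with the four long-tailed metrics
#: entering on the natural-log scale.
MODEL_VARIABLES: tuple[str, ...] = (
    "age",
    "stage_group",
    "treatment",
    "suv_max",
    "suv_mean",
    "mtv_ml",
    "log_tlg",
    "hist_sd",
    "hist_entropy",
    "log_hist_energy",
    "hist_skewness",
    "hist_kurtosis",
    "log_glcm_homogeneity",
    "glcm_entropy",
    "glcm_dissimilarity",
    "log_ngtdm_coarseness",
    "glszm_intensity_variability",
    "glszm_large_area_emphasis",
    "glszm_zone_percentage",
)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity description of one synthetic tumour phantom."""

    shape: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)  # mm
    semi_axes: tuple[float, float, float] = (20.0, 16.0, 14.0)  # mm
    centre: tuple[float, float, float] | None = None  # mm; default = grid centre
    tumour_suv: float = 8.0
    background_suv: float = 1.0
    heterogeneity_sd: float = 0.0  # SUV
    correlation_length: float = 8.0  # mm
    noise_sd: float = 0.0  # SUV
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.tumour_suv > self.background_suv > 0):
            raise ValidationError(
                "need tumour SUV > background SUV > 0, got "
                f"{self.tumour_suv} / {self.background_suv}"
            )
        if self.correlation_length <= 0:
            raise ValidationError("correlation length must be > 0")
        if self.noise_sd < 0 or self.heterogeneity_sd < 0:
            raise ValidationError("noise/heterogeneity sd must be >= 0")

    @property
    def tbr(self) -> float:
        """Tumour-to-background ratio of the noise-free means."""
        return self.tumour_suv / self.background_suv


def generate_phantom(spec: PhantomSpec) -> tuple[PETVolume, BinaryMask]:
    """Build one phantom volume and its ground-truth tumour mask.

    The volume is ``background + ellipsoid*(tumour-background) + correlated
    field (tumour only) + white noise``, clipped at 0.  The correlated field
    is white noise smoothed with a Gaussian kernel of sigma equal to the
    correlation length and rescaled to the requested standard deviation.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    extent = (np.asarray(shape) - 1) * spacing
    centre = (
        np.asarray(spec.centre, dtype=float)
        if spec.centre is not None
        else extent / 2.0
    )
    semi = np.asarray(spec.semi_axes, dtype=float)
    if np.any(centre - semi < 0) or np.any(centre + semi > extent):
        raise GeometryError(
            f"tumour (centre {tuple(centre)}, semi-axes {tuple(semi)}) "
            f"extends outside the grid extent {tuple(extent)}"
        )

    coords = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    r2 = sum(((c - mu) / a) ** 2 for c, mu, a in zip(coords, centre, semi))
    tumour = r2 <= 1.0

    vol = np.full(shape, spec.background_suv, dtype=float)
    vol[tumour] = spec.tumour_suv

    # correlated heterogeneity, restricted to the tumour
    white = rng.standard_normal(shape)
    sigma_vox = spec.correlation_length / spacing
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
    sd = smooth[tumour].std() if tumour.any() else 0.0
    if spec.heterogeneity_sd > 0 and sd > 0:
        vol[tumour] += smooth[tumour] / sd * spec.heterogeneity_sd

    noise = rng.standard_normal(shape)
    if spec.noise_sd > 0:
        vol += spec.noise_sd * noise

    np.clip(vol, 0.0, None, out=vol)
    spacing_t = tuple(float(s) for s in spacing)
    return (
        PETVolume(vol, spacing_t),
        BinaryMask(tumour.astype(np.uint8), spacing_t),
    )


#: Imaging regimes sampled by :func:`phantom_suite`:
#: (TBR range, noise-sd range, heterogeneity-sd range).  Together they span
#: avid/clean, faint/clean, noisy and heterogeneous lesions — the regimes in
#: which the PET-AS method bank's members fail in complementary ways.
PHANTOM_REGIMES: tuple[tuple[tuple[float, float], ...], ...] = (
    ((4.0, 10.0), (0.05, 0.25), (0.0, 0.5)),  # avid, clean
    ((2.0, 2.6), (0.02, 0.10), (0.0, 0.3)),  # faint, clean
    ((3.0, 8.0), (0.60, 1.10), (0.0, 0.5)),  # noisy
    ((2.5, 8.0), (0.05, 0.40), (0.8, 1.5)),  # heterogeneous
)


def phantom_suite(
    n: int,
    seed: int,
    shape: tuple[int, int, int] = (32, 32, 32),
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0),
    semi_axis_range: tuple[float, float] = (10.0, 30.0),
    regimes=PHANTOM_REGIMES,
) -> list[PhantomSpec]:
    """Sample ``n`` phantom specs stratified over imaging regimes.

    Phantoms cycle through :data:`PHANTOM_REGIMES` so every suite covers
    faint through avid and clean through noisy/heterogeneous lesions with
    equal mass; sizes vary uniformly within each regime.  Used to train and
    evaluate the segmentation-method selector.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        tbr_range, noise_range, het_range = regimes[i % len(regimes)]
        tbr = rng.uniform(*tbr_range)
        background = 1.0
        semi = rng.uniform(*semi_axis_range, size=3)
        specs.append(
            PhantomSpec(
                shape=shape,
                spacing=spacing,
                semi_axes=tuple(semi),
                tumour_suv=background * tbr,
                background_suv=background,
                heterogeneity_sd=float(rng.uniform(*het_range)),
                correlation_length=float(rng.uniform(6.0, 14.0)),
                noise_sd=float(rng.uniform(*noise_range)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


@dataclass(frozen=True)
class SimulationConfig:
    """Survival-cohort simulation settings.

    Defaults mimic the development cohort's marginals: age uniform 39-84,
    stage-group probabilities 17/56/160/69 out of 302, curative treatment
    probability 158/302, median OS near 16 months and roughly three quarters
    of patients dead by end of follow-up.
    """

    n: int = 302
    coefficients: dict = field(default_factory=lambda: dict(PUBLISHED_COEFFICIENTS))
    baseline_hazard: float = np.log(2) / 16.0  # per month; median OS 16 months
    censoring_rate: float = 0.008  # per month
    admin_cutoff: float = 72.0  # months
    age_range: tuple[float, float] = (39.0, 84.0)
    stage_probs: tuple[float, ...] = (17 / 302, 56 / 302, 160 / 302, 69 / 302)
    curative_prob: float = 158 / 302
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 8:
            raise ValidationError("need n >= 8 (two patients per quartile)")
        if self.baseline_hazard <= 0 or self.censoring_rate <= 0:
            raise ValidationError("hazard and censoring rates must be > 0")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9 or len(self.stage_probs) != 4:
            raise ValidationError("stage_probs must be 4 probabilities summing to 1")


def simulate_survival(
    linear_predictor: np.ndarray, config: SimulationConfig, rng=None
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (os_months, event) under proportional hazards.

    Event times are exponential with rate ``baseline * exp(lp - mean(lp))``
    (centring keeps the event fraction stable across coefficient choices);
    censoring is exponential at ``censoring_rate`` truncated at the
    administrative cutoff; the observed time is the minimum, with ``event = 1``
    when the death time comes first.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValidationError("linear predictors must be finite")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rate = config.baseline_hazard * np.exp(lp - lp.mean())
    t_event = rng.exponential(1.0 / rate)
    t_cens = np.minimum(
        rng.exponential(1.0 / config.censoring_rate, size=lp.shape),
        config.admin_cutoff,
    )
    os_months = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    # os_months must be strictly positive for downstream validation
    np.clip(os_months, 1e-6, None, out=os_months)
    return os_months, event


# (mean, sd, loading on latent size factor, loading on latent heterogeneity
# factor) for each feature generated on its transformed (model) scale.
# Scales are a priori choices plausible for FDG-avid oesophageal tumours;
# the published study reports no feature distributions.
_FEATURE_FACTORS: dict[str, tuple[float, float, float, float]] = {
    "log_mtv": (2.8, 0.55, 0.80, 0.00),
    "log_suv_mean": (1.60, 0.30, 0.48, 0.10),
    "log_suv_max_minus_mean": (-0.90, 0.35, 0.10, 0.30),
    "hist_sd": (1.30, 0.35, 0.20, 0.50),
    "hist_entropy": (4.00, 0.80, 0.55, 0.30),
    "log_hist_energy": (-2.50, 0.50, -0.45, -0.35),
    "hist_skewness": (0.40, 0.50, 0.00, 0.30),
    "log_hist_kurtosis_minus_1": (0.55, 0.55, 0.00, 0.30),
    "log_glcm_homogeneity": (-0.70, 0.25, -0.20, -0.40),
    "glcm_entropy": (6.00, 1.00, 0.50, 0.35),
    "glcm_dissimilarity": (1.50, 0.50, 0.20, 0.55),
    "log_ngtdm_coarseness": (-4.00, 0.80, -0.55, -0.30),
    "log_glszm_intensity_variability": (2.00, 0.70, 0.60, 0.20),
    "log_glszm_large_area_emphasis": (3.00, 1.00, 0.55, -0.35),
    "logit_glszm_zone_percentage": (-1.00, 0.80, -0.45, 0.40),
}


def _draw_features(n: int, rng) -> pd.DataFrame:
    """Draw the 16 PET metrics via a two-factor latent model.

    A latent "size/avidity" factor and a latent "heterogeneity" factor induce
    realistic collinearity (e.g. between MTV, TLG and SUV statistics) while
    keeping every marginal easy to state.  Raw-scale columns are recovered by
    inverting the transforms; TLG = SUVmean x MTV holds exactly.
    """
    f_size = rng.standard_normal(n)
    f_het = rng.standard_normal(n)
    t = {}
    for name, (mean, sd, a, b) in _FEATURE_FACTORS.items():
        c = np.sqrt(max(1.0 - a * a - b * b, 0.0))
        t[name] = mean + sd * (a * f_size + b * f_het + c * rng.standard_normal(n))

    df = pd.DataFrame(index=range(n))
    df["mtv_ml"] = np.exp(t["log_mtv"])
    df["suv_mean"] = np.exp(t["log_suv_mean"])
    df["tlg"] = df["suv_mean"] * df["mtv_ml"]
    df["suv_max"] = df["suv_mean"] * (1.0 + np.exp(t["log_suv_max_minus_mean"]))
    df["hist_sd"] = np.maximum(t["hist_sd"], 0.05)
    df["hist_entropy"] = np.maximum(t["hist_entropy"], 0.1)
    df["hist_energy"] = np.exp(np.minimum(t["log_hist_energy"], 0.0))
    df["hist_skewness"] = t["hist_skewness"]
    df["hist_kurtosis"] = 1.0 + np.exp(t["log_hist_kurtosis_minus_1"])
    df["glcm_homogeneity"] = np.exp(np.minimum(t["log_glcm_homogeneity"], -0.01))
    df["glcm_entropy"] = np.maximum(t["glcm_entropy"], 0.1)
    df["glcm_dissimilarity"] = np.maximum(t["glcm_dissimilarity"], 0.05)
    df["ngtdm_coarseness"] = np.exp(t["log_ngtdm_coarseness"])
    df["glszm_intensity_variability"] = np.exp(t["log_glszm_intensity_variability"])
    df["glszm_large_area_emphasis"] = np.exp(t["log_glszm_large_area_emphasis"])
    df["glszm_zone_percentage"] = 1.0 / (1.0 + np.exp(-t["logit_glszm_zone_percentage"]))
    return df


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a complete analysis-ready cohort table.

    Columns: id, age, stage_group, treatment, os_months, event and the 16 PET
    metrics on their raw scale.  The survival linear predictor is
    ``sum(coefficient * variable)`` over ``config.coefficients``, where
    variables named ``log_*``/``logit_*`` refer to the transformed scale.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    df = _draw_features(n, rng)
    df.insert(0, "id", [f"p{i + 1:04d}" for i in range(n)])
    df.insert(1, "age", rng.uniform(*config.age_range, size=n).round(1))
    df.insert(2, "stage_group", rng.choice([1, 2, 3, 4], size=n, p=config.stage_probs))
    df.insert(3, "treatment", np.where(rng.random(n) < config.curative_prob, 1, 2))

    model_cols = _model_matrix(df)
    lp = np.zeros(n)
    for name, beta in config.coefficients.items():
        if beta == 0.0:
            continue
        if name not in model_cols:
            raise ValidationError(f"unknown coefficient variable: {name}")
        lp += beta * model_cols[name].to_numpy()

    os_months, event = simulate_survival(lp, config, rng=rng)
    df.insert(4, "os_months", np.round(os_months, 3))
    df.insert(5, "event", event)
    return df


def _model_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Transformed model-variable columns derived from a raw cohort table."""
    cols = pd.DataFrame(index=df.index)
    for v in ("age", "stage_group", "treatment", "suv_max", "suv_mean", "mtv_ml",
              "hist_sd", "hist_entropy", "hist_skewness", "hist_kurtosis",
              "glcm_entropy", "glcm_dissimilarity",
              "glszm_intensity_variability", "glszm_large_area_emphasis",
              "glszm_zone_percentage"):
        if v in df:
            cols[v] = df[v].astype(float)
    for raw, logname in (("tlg", "log_tlg"),
                         ("hist_energy", "log_hist_energy"),
                         ("ngtdm_coarseness", "log_ngtdm_coarseness"),
                         ("glcm_homogeneity", "log_glcm_homogeneity")):
        if raw in df:
            cols[logname] = np.log(df[raw].astype(float))
    return cols
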