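"""Repeatable simulation studies over the synthetic generators.

These functions are the quantitative backbone of the test suite and of the
reproduction script: each runs a seeded Monte-Carlo study of one pipeline
property (coefficient recovery, variable-selection power, interaction-test
calibration, AIC model ordering, segmentation-selector gain) and returns
plain numbers.  Replicate seeds are spawned deterministically from the one
seed argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segmentation import (
    METHODS,
    dice,
    score_methods,
    select_and_segment,
    train_selector,
    BoundingBox,
)
from .survival import (
    PrognosticModel,
    assign_quartiles,
    backward_eliminate,
    compare_models,
    fit_cox,
    interaction_test,
    logrank_test,
    prognostic_score,
)
from .synthetic import (
    MODEL_VARIABLES,
    PUBLISHED_COEFFICIENTS,
    PhantomSpec,
    SimulationConfig,
    _model_matrix,
    generate_cohort,
    generate_phantom,
    phantom_suite,
    simulate_survival,
)

TRUE_TEXTURE_VARIABLES = ("log_tlg", "log_hist_energy", "hist_kurtosis")


def crop_to_lesion(volume, truth, box: BoundingBox | None = None):
    """Crop a phantom and its truth mask to a snug manual-style box."""
    from .io import BinaryMask
    from .segmentation import crop

    if box is None:
        box = BoundingBox.around_mask(truth)
    cvol = crop(volume, box)
    ctruth = BinaryMask(
        truth.voxels[box.slices].astype(np.uint8), cvol.spacing, cvol.origin
    )
    return cvol, ctruth


def _rep_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def model_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Outcome columns plus the 19 transformed model variables."""
    return pd.concat(
        [cohort[["os_months", "event"]].reset_index(drop=True),
         _model_matrix(cohort).reset_index(drop=True)],
        axis=1,
    )


def hr_recovery(seed: int, n: int = 10_000, true_hr: float = 2.0) -> dict:
    """Fit a two-group Cox model on data with a known hazard ratio.

    Returns the estimate, its SE, and the deviation |beta - log(HR)| in SE
    units; large-sample theory puts that deviation within 3 almost always.
    """
    rng = np.random.default_rng(seed)
    group = (rng.random(n) < 0.5).astype(float)
    config = SimulationConfig(n=n, coefficients={}, seed=int(rng.integers(2**31)))
    os_months, event = simulate_survival(
        np.log(true_hr) * group, config, rng=rng
    )
    table = pd.DataFrame({"os_months": os_months, "event": event, "group": group})
    fit = fit_cox(table, ["group"])
    beta, se = float(fit.beta[0]), float(fit.se[0])
    return {
        "beta": beta,
        "se": se,
        "z_deviation": abs(beta - np.log(true_hr)) / se,
        "n": n,
    }


def elimination_retention_rate(
    n_reps: int = 200,
    n: int = 302,
    seed: int = 0,
    coefficients: dict | None = None,
    alpha_remove: float = 0.05,
) -> dict:
    """Share of replicates whose backward elimination keeps all three truly
    prognostic texture variables (and, separately, each one marginally)."""
    coefficients = dict(PUBLISHED_COEFFICIENTS if coefficients is None else coefficients)
    seeds = _rep_seeds(seed, n_reps)
    kept_all = 0
    kept_each = {v: 0 for v in TRUE_TEXTURE_VARIABLES}
    n_retained = []
    for s in seeds:
        cohort = generate_cohort(
            SimulationConfig(n=n, coefficients=coefficients, seed=int(s))
        )
        res = backward_eliminate(
            model_table(cohort), MODEL_VARIABLES, alpha_remove=alpha_remove
        )
        retained = set(res.fit.variables)
        n_retained.append(len(retained))
        for v in TRUE_TEXTURE_VARIABLES:
            kept_each[v] += v in retained
        kept_all += all(v in retained for v in TRUE_TEXTURE_VARIABLES)
    return {
        "rate_all_three": kept_all / n_reps,
        "rate_each": {v: k / n_reps for v, k in kept_each.items()},
        "mean_model_size": float(np.mean(n_retained)),
        "n_reps": n_reps,
    }


def null_elimination_sizes(n_reps: int = 50, n: int = 302, seed: int = 0) -> list[int]:
    """Final model sizes when every generating coefficient is zero."""
    sizes = []
    for s in _rep_seeds(seed, n_reps):
        cohort = generate_cohort(SimulationConfig(n=n, coefficients={}, seed=int(s)))
        res = backward_eliminate(model_table(cohort), MODEL_VARIABLES)
        sizes.append(res.fit.k)
    return sizes


def interaction_rejection_rate(
    n_reps: int = 500,
    n: int = 150,
    gamma: float = 0.0,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the score x treatment interaction test.

    ``gamma`` is the generating interaction coefficient on the centred score:
    0 gives the type-I error (should sit near alpha), large values give power.
    """
    model = PrognosticModel()
    rejections = 0
    for s in _rep_seeds(seed, n_reps):
        config = SimulationConfig(n=n, seed=int(s))
        cohort = generate_cohort(config)
        score = prognostic_score(cohort, model).to_numpy()
        if gamma != 0.0:
            rng = np.random.default_rng(int(s) ^ 0x5EED)
            sc = score - score.mean()
            lp = _linear_predictor(cohort, config.coefficients)
            lp = lp + gamma * sc * (cohort["treatment"].to_numpy() - 1.5)
            os_months, event = simulate_survival(lp, config, rng=rng)
            cohort = cohort.assign(os_months=os_months, event=event)
        res = interaction_test(cohort, score)
        rejections += res.p < alpha
    return {"rate": rejections / n_reps, "n_reps": n_reps, "gamma": gamma}


def _linear_predictor(cohort: pd.DataFrame, coefficients: dict) -> np.ndarray:
    cols = _model_matrix(cohort)
    lp = np.zeros(len(cohort))
    for name, beta in coefficients.items():
        lp += beta * cols[name].to_numpy()
    return lp


def aic_ordering_rate(n_reps: int = 100, n: int = 302, seed: int = 0) -> dict:
    """How often the full texture model attains the strictly lowest AIC
    when texture effects are truly present in the generator."""
    wins = 0
    for s in _rep_seeds(seed, n_reps):
        cohort = generate_cohort(SimulationConfig(n=n, seed=int(s)))
        cmp = compare_models(model_table(cohort))
        best = cmp.loc[cmp["aic"].idxmin(), "model"]
        wins += best == "clinical+suv+texture"
    return {"rate": wins / n_reps, "n_reps": n_reps}


def null_quartile_nonsignificance_rate(
    n_reps: int = 100, n: int = 302, seed: int = 0, alpha: float = 0.05
) -> dict:
    """With all generating coefficients zero, score quartiles should show no
    OS difference; returns the share of replicates with log-rank p >= alpha."""
    model = PrognosticModel()
    nonsig = 0
    for s in _rep_seeds(seed, n_reps):
        cohort = generate_cohort(SimulationConfig(n=n, coefficients={}, seed=int(s)))
        score = prognostic_score(cohort, model).to_numpy()
        labels, _ = assign_quartiles(score)
        res = logrank_test(cohort["os_months"], cohort["event"], labels)
        nonsig += res.p >= alpha
    return {"rate": nonsig / n_reps, "n_reps": n_reps}


def coefficient_coverage(
    n_reps: int = 500, n: int = 302, seed: int = 0
) -> dict:
    """95% CI coverage of each true generating coefficient, fitting the
    six-variable score model on fresh cohorts."""
    truth = PUBLISHED_COEFFICIENTS
    variables = list(truth)
    hits = {v: 0 for v in variables}
    for s in _rep_seeds(seed, n_reps):
        cohort = generate_cohort(SimulationConfig(n=n, seed=int(s)))
        fit = fit_cox(model_table(cohort), variables)
        for v, b, se in zip(fit.variables, fit.beta, fit.se):
            if b - 1.96 * se <= truth[v] <= b + 1.96 * se:
                hits[v] += 1
    return {
        "coverage": {v: h / n_reps for v, h in hits.items()},
        "n_reps": n_reps,
    }


def validation_power(
    n_reps: int = 50, n_dev: int = 302, n_val: int = 101, seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Power of the frozen-model validation log-rank test at the validation
    cohort size, with development and validation cohorts drawn from the same
    generative model."""
    from .survival import validate_model

    model = PrognosticModel()
    sig = 0
    seeds = _rep_seeds(seed, n_reps * 2).reshape(n_reps, 2)
    for s_dev, s_val in seeds:
        dev = generate_cohort(SimulationConfig(n=n_dev, seed=int(s_dev)))
        dev_scores = prognostic_score(dev, model).to_numpy()
        _, cutoffs = assign_quartiles(dev_scores)
        frozen = model.with_cutoffs(cutoffs)
        val = generate_cohort(SimulationConfig(n=n_val, seed=int(s_val)))
        report = validate_model(frozen, val)
        sig += report.logrank.p < alpha
    return {"rate": sig / n_reps, "n_reps": n_reps}


def selector_holdout_study(
    n_train: int = 120, n_test: int = 50, seed: int = 0
) -> dict:
    """Train the method selector and compare it with each fixed method on a
    held-out phantom suite.

    Returns mean Dice per fixed method, mean Dice of the selected method,
    and the per-phantom Dice table.
    """
    train_specs = phantom_suite(n_train, seed=seed)
    test_specs = phantom_suite(n_test, seed=seed + 1)
    train = [crop_to_lesion(*generate_phantom(sp)) for sp in train_specs]
    selector = train_selector(train)

    rows = []
    for sp in test_specs:
        vol, truth = generate_phantom(sp)
        box = BoundingBox.around_mask(truth)
        cvol, ctruth = crop_to_lesion(vol, truth, box)
        scores = score_methods(cvol, ctruth)
        result = select_and_segment(vol, box, selector)
        rows.append(
            {
                "selected_method": result.method,
                "selected_dice": dice(result.mask, truth),
                **{f"dice_{m}": scores[m] for m in METHODS},
            }
        )
    table = pd.DataFrame(rows)
    return {
        "mean_selected_dice": float(table["selected_dice"].mean()),
        "mean_method_dice": {
            m: float(table[f"dice_{m}"].mean()) for m in METHODS
        },
        "table": table,
    }
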