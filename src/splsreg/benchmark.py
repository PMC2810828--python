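"""Ready-made tune->fit->predict pipelines for the benchmark runner.

Each factory returns a callable ``method(dataset) -> (coef_full,
Y_pred_test)`` suitable for :func:`splsreg.run_table_experiment`.
External comparator methods can be benchmarked by passing any callable
with the same signature.
"""

from __future__ import annotations

import numpy as np

from .data import center_scale
from .model import fit_spls, predict_spls
from .simulate import SimulatedDataset
from .tuning import fit_spls_fdr, kfold_cv_spls, kfold_cv_spls_fdr

__all__ = [
    "method_spls_cv",
    "method_spls_fdr",
    "selection_experiment",
    "block_cv_experiment",
    "block_fdr_experiment",
    "one_component_experiment",
]


def method_spls_cv(
    k_max: int = 5,
    eta_grid=None,
    rule: str = "parsimony_1.1",
    folds: int = 10,
    kappa: float = 0.4,
    variant: str = "nipals",
):
    """CV-tuned soft-thresholded SPLS (eta and K chosen per run)."""
    if eta_grid is None:
        eta_grid = np.round(np.arange(0.1, 1.0, 0.1), 1)

    def method(ds: SimulatedDataset):
        cv = kfold_cv_spls(
            ds.X_train, ds.Y_train, eta_grid=eta_grid,
            K_grid=range(1, k_max + 1), folds=folds, rule=rule,
            seed=ds.config.seed, kappa=kappa, variant=variant,
        )
        data = center_scale(ds.X_train, ds.Y_train)
        fit = fit_spls(
            data, K=cv.chosen_K, eta=cv.chosen_eta, kappa=kappa, variant=variant
        )
        return fit.coef_full, predict_spls(fit, ds.X_test, data)

    return method


def selection_experiment(variant: str, n_runs: int = 100, seed: int = 0):
    """Variable-selection study on the multivariate response-chain design.

    Per run: CV-tune (eta, K) under the plain minimum rule (the CV
    surface is not flat here), fit, and count selected variables inside
    and outside the 13 relevant columns.  Returns the per-run
    EvalReport list; Table-1-style summaries are quartiles of the
    correct/incorrect counts.
    """
    from .simulate import run_table_experiment

    method = method_spls_cv(k_max=5, rule="min", variant=variant)
    return run_table_experiment("s51_multi", n_runs, seed, method)


def block_cv_experiment(n_runs: int = 30, seed: int = 0):
    """CV-tuned SPLS on the small-n grouped design (p=80, n=40, 20
    spurious, noise-to-signal 0.1); returns per-run EvalReports."""
    from .simulate import run_table_experiment

    method = method_spls_cv(k_max=5, rule="parsimony_1.1")
    return run_table_experiment(
        "s53_block", n_runs, seed, method,
        overrides={"n": 40, "p": 80, "q_spurious": 20, "noise_to_signal": 0.1},
    )


def block_fdr_experiment(n_runs: int = 30, seed: int = 0, alpha: float = 0.1):
    """FDR-tuned SPLS on the large-n grouped design (p=40, n=400, 10
    spurious, noise-to-signal 0.1); returns per-run EvalReports."""
    from .simulate import run_table_experiment

    method = method_spls_fdr(alpha=alpha, k_max=5)
    return run_table_experiment(
        "s53_block", n_runs, seed, method,
        overrides={"n": 400, "p": 40, "q_spurious": 10,
                   "noise_to_signal": 0.1},
    )


def one_component_experiment(n_runs: int = 30, seed: int = 0):
    """Single-component CV-tuned SPLS on the p=5000 multi-latent design
    (several hidden components, fits restricted to K=1)."""
    from .simulate import run_table_experiment

    method = method_spls_cv(k_max=1, rule="parsimony_1.1")
    return run_table_experiment("s54_sim3", n_runs, seed, method)


def method_spls_fdr(
    alpha: float = 0.1,
    k_max: int = 5,
    rule: str = "parsimony_1.1",
    folds: int = 10,
    variant: str = "nipals",
):
    """FDR-thresholded SPLS at level alpha with CV-chosen K (univariate)."""

    def method(ds: SimulatedDataset):
        cv = kfold_cv_spls_fdr(
            ds.X_train, ds.Y_train, alpha=alpha, K_grid=range(1, k_max + 1),
            folds=folds, rule=rule, seed=ds.config.seed, variant=variant,
        )
        data = center_scale(ds.X_train, ds.Y_train)
        fit = fit_spls_fdr(data, K=cv.chosen_K, alpha=alpha, variant=variant)
        return fit.coef_full, predict_spls(fit, ds.X_test, data)

    return method
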