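"""Per-gene model fitting: integrative (all feature types stacked under one
L1 penalty) and single-type modes, plus cross-validated prediction accuracy.

For each gene k the centered trait y_k is regressed on the standardized
feature blocks.  In integrative mode the blocks are concatenated in the fixed
order (CNA, methylation, miRNA) -- because a single penalty applies to the
whole coefficient vector, the optimum does not depend on this order -- and
the Screen-and-Clean procedure runs once on the stacked design.  In single
mode it runs on one block at a time.  Association strength is the magnitude
of the clean-stage coefficient (features standardized).

Prediction accuracy is the Pearson correlation between observed traits and
pooled held-out predictions from a K-fold scheme in which selection and
estimation are re-run within every training split; associations weaker than
``rho_accuracy`` are discarded and the surviving features refit by OLS
before predicting, mirroring the downstream strength filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .omics_io import CNA, METHYLATION, MIRNA, MultiOmicsDataset
from .sparse import CleanResult, screen_and_clean, _ols_t_tests

BLOCK_ORDER = (CNA, METHYLATION, MIRNA)

MODE_INTEGRATIVE = "integrative"
SINGLE_MODES = tuple(f"single:{t}" for t in BLOCK_ORDER)
ALL_MODES = (MODE_INTEGRATIVE,) + SINGLE_MODES


@dataclass
class FitConfig:
    """Knobs of the per-gene procedure, all reproducibility-relevant.

    seed: global seed; per-gene seeds derive from (seed, gene index) so the
    fits are independent and identical regardless of execution order.
    """

    alpha: float = 0.05
    split_fraction: float = 0.5
    cv_folds: int = 10
    n_lambda: int = 60
    lambda_min_ratio: float = 1e-2
    accuracy_folds: int = 5
    rho_accuracy: float = 0.1
    seed: int = 0
    block_order: tuple[str, ...] = BLOCK_ORDER

    def as_dict(self) -> dict:
        d = asdict(self)
        d["block_order"] = list(self.block_order)
        return d


@dataclass
class SparseFit:
    """Fitted sparse model for one gene in one mode.

    ``beta``/``p_values`` map feature type -> dense per-feature arrays
    (zeros / NaN where unselected) so coefficients stay attached to their
    block.  ``accuracy`` is the cross-validated Pearson correlation;
    ``in_sample_accuracy`` the optimistic within-sample one.
    """

    gene_id: str
    mode: str
    beta: dict[str, np.ndarray]
    p_values: dict[str, np.ndarray]
    lam: float
    accuracy: float = float("nan")
    in_sample_accuracy: float = float("nan")
    flags: list[str] = field(default_factory=list)
    clean: CleanResult | None = None

    @property
    def n_selected(self) -> int:
        return int(sum((b != 0).sum() for b in self.beta.values()))

    def selected_types(self) -> frozenset[str]:
        return frozenset(t for t, b in self.beta.items() if np.any(b != 0))


@dataclass
class FitResults:
    """One mode's fits over all genes plus run metadata."""

    mode: str
    fits: dict[str, SparseFit]
    skipped: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.fits.values())


def mode_types(mode: str) -> tuple[str, ...]:
    if mode == MODE_INTEGRATIVE:
        return BLOCK_ORDER
    if mode.startswith("single:"):
        t = mode.split(":", 1)[1]
        if t not in BLOCK_ORDER:
            raise ValueError(f"unknown feature type in mode '{mode}'")
        return (t,)
    raise ValueError(f"unknown mode '{mode}'; expected one of {ALL_MODES}")


def stacked_design(
    dataset: MultiOmicsDataset, types: tuple[str, ...]
) -> tuple[np.ndarray, list[tuple[str, int, str]]]:
    """Concatenate the requested (normalized) blocks column-wise.

    Returns the N x sum(J_m) design and a column index of
    (feature_type, within-block position, feature_id) triples.
    """
    mats = []
    index: list[tuple[str, int, str]] = []
    for t in types:
        if t not in dataset.blocks:
            continue
        blk = dataset.blocks[t]
        if not blk.normalized:
            raise ValueError(f"block '{t}' must be z-score normalized before fitting")
        if blk.n_features == 0:
            raise ValueError(f"block '{t}' has no features")
        mats.append(blk.values)
        index.extend((t, j, fid) for j, fid in enumerate(blk.feature_ids))
    if not mats:
        raise ValueError(f"no requested block present in dataset: {types}")
    return np.hstack(mats), index


def _gene_seed(seed: int, gene_index: int, stream: int = 0) -> int:
    ss = np.random.SeedSequence((int(seed), int(gene_index), int(stream)))
    return int(ss.generate_state(1)[0] % (2**31))


def _gene_index(dataset: MultiOmicsDataset, gene_id: str) -> int:
    try:
        return dataset.expression.gene_ids.index(gene_id)
    except ValueError:
        raise KeyError(f"gene '{gene_id}' not in expression matrix") from None


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _unpack(
    dataset: MultiOmicsDataset,
    types: tuple[str, ...],
    index: list[tuple[str, int, str]],
    clean: CleanResult,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    beta = {
        t: np.zeros(dataset.blocks[t].n_features) for t in types if t in dataset.blocks
    }
    pvals = {
        t: np.full(dataset.blocks[t].n_features, np.nan)
        for t in types
        if t in dataset.blocks
    }
    for col, b, p in zip(clean.selected, clean.coefficients, clean.p_values):
        t, j, _ = index[col]
        beta[t][j] = b
        pvals[t][j] = p
    return beta, pvals


def fit_gene(
    dataset: MultiOmicsDataset,
    gene_id: str,
    mode: str,
    config: FitConfig | None = None,
    compute_accuracy: bool = True,
) -> SparseFit:
    """Fit one gene in one mode via lasso Screen-and-Clean."""
    config = config or FitConfig()
    gi = _gene_index(dataset, gene_id)
    if dataset.expression.sigma[gi] == 0.0:
        return SparseFit(
            gene_id=gene_id, mode=mode, beta={}, p_values={}, lam=float("nan"),
            flags=["zero_variance_skipped"],
        )
    types = mode_types(mode)
    X, index = stacked_design(dataset, types)
    y = dataset.expression.values[gi]
    y = y - y.mean()

    clean = screen_and_clean(
        X, y,
        alpha=config.alpha,
        split_fraction=config.split_fraction,
        seed=_gene_seed(config.seed, gi),
        cv_folds=config.cv_folds,
        n_lambda=config.n_lambda,
        min_ratio=config.lambda_min_ratio,
    )
    present = tuple(t for t in types if t in dataset.blocks)
    beta, pvals = _unpack(dataset, present, index, clean)
    fit = SparseFit(
        gene_id=gene_id, mode=mode, beta=beta, p_values=pvals,
        lam=clean.lam, clean=clean,
    )
    if clean.truncated:
        fit.flags.append("screen_set_truncated")
    if clean.dropped_collinear:
        fit.flags.append("collinear_dropped")

    if clean.selected.size:
        yhat = X[:, clean.selected] @ clean.coefficients
        r = _pearson(yhat, y)
        fit.in_sample_accuracy = 0.0 if np.isnan(r) else r
    else:
        fit.in_sample_accuracy = 0.0
        fit.flags.append("no_model")

    if compute_accuracy:
        acc, acc_flags = prediction_accuracy(dataset, gene_id, mode, config)
        fit.accuracy = acc
        fit.flags.extend(acc_flags)
    return fit


def fit_gene_integrative(
    dataset: MultiOmicsDataset, gene_id: str, config: FitConfig | None = None, **kw
) -> SparseFit:
    return fit_gene(dataset, gene_id, MODE_INTEGRATIVE, config, **kw)


def fit_gene_single(
    dataset: MultiOmicsDataset,
    gene_id: str,
    type_label: str,
    config: FitConfig | None = None,
    **kw,
) -> SparseFit:
    return fit_gene(dataset, gene_id, f"single:{type_label}", config, **kw)


def prediction_accuracy(
    dataset: MultiOmicsDataset,
    gene_id: str,
    mode: str,
    config: FitConfig | None = None,
    force_features: list[int] | None = None,
) -> tuple[float, list[str]]:
    """K-fold cross-validated Pearson correlation between the trait and
    pooled held-out predictions.

    Within each fold, Screen-and-Clean selection is re-run on the training
    samples, associations weaker than ``rho_accuracy`` dropped, survivors
    refit by OLS, and the held-out samples predicted.  ``force_features``
    bypasses selection with a fixed column set (diagnostic use).  Returns
    (accuracy, flags); constant pooled predictions flag the accuracy as
    undefined and score 0.

    Predictions carry no fold-specific intercept: Pearson correlation is
    translation-invariant, and a fold-varying training-mean offset would
    anti-correlate with the held-out responses, biasing null-model
    accuracies negative.
    """
    config = config or FitConfig()
    gi = _gene_index(dataset, gene_id)
    types = mode_types(mode)
    X, _ = stacked_design(dataset, types)
    y = dataset.expression.values[gi].astype(float)
    N = y.shape[0]
    k = config.accuracy_folds
    if N < 2 * k:
        raise ValueError(f"need N >= {2 * k} samples for {k}-fold accuracy")

    rng = np.random.default_rng(
        np.random.SeedSequence((int(config.seed), int(gi), 7))
    )
    perm = rng.permutation(N)
    folds = np.array_split(perm, k)
    yhat = np.empty(N)
    flags: list[str] = []
    any_model = False
    for f, val in enumerate(folds):
        mask = np.ones(N, dtype=bool)
        mask[val] = False
        Xtr, ytr = X[mask], y[mask]
        xm = Xtr.mean(axis=0)
        ym = ytr.mean()
        Xtr_c = Xtr - xm
        ytr_c = ytr - ym
        if force_features is not None:
            survivors = np.asarray(force_features, int)
        elif np.var(ytr_c) == 0.0:
            survivors = np.array([], int)
        else:
            clean = screen_and_clean(
                Xtr_c, ytr_c,
                alpha=config.alpha,
                split_fraction=config.split_fraction,
                seed=_gene_seed(config.seed, gi, stream=100 + f),
                cv_folds=config.cv_folds,
                n_lambda=config.n_lambda,
                min_ratio=config.lambda_min_ratio,
            )
            strong = np.abs(clean.coefficients) >= config.rho_accuracy
            survivors = clean.selected[strong]
        if survivors.size == 0:
            yhat[val] = 0.0
            continue
        keep, beta, _, _ = _ols_t_tests(Xtr_c[:, survivors], ytr_c)
        if keep.size == 0:
            yhat[val] = 0.0
            continue
        any_model = True
        yhat[val] = (X[val][:, survivors[keep]] - xm[survivors[keep]]) @ beta

    if not any_model:
        # no fold ever produced a model; only fold means were predicted and
        # their tiny spread carries no information
        return 0.0, ["no_model_in_any_fold"]
    r = _pearson(yhat, y)
    if np.isnan(r):
        flags.append("accuracy_undefined_constant_prediction")
        return 0.0, flags
    return r, flags


def fit_all_genes(
    dataset: MultiOmicsDataset,
    mode: str,
    config: FitConfig | None = None,
    gene_ids: list[str] | None = None,
    compute_accuracy: bool = True,
) -> FitResults:
    """Independent per-gene fits; deterministic regardless of gene order.

    Per-gene failures are collected into ``skipped`` rather than aborting.
    """
    config = config or FitConfig()
    mode_types(mode)  # validate early
    genes = gene_ids if gene_ids is not None else dataset.expression.gene_ids
    fits: dict[str, SparseFit] = {}
    skipped: dict[str, str] = {}
    for g in genes:
        gi = _gene_index(dataset, g)
        if dataset.expression.sigma[gi] == 0.0:
            skipped[g] = "zero variance trait"
            continue
        try:
            fits[g] = fit_gene(dataset, g, mode, config, compute_accuracy=compute_accuracy)
        except Exception as exc:  # pragma: no cover - defensive aggregation
            skipped[g] = f"{type(exc).__name__}: {exc}"
    return FitResults(
        mode=mode,
        fits=fits,
        skipped=skipped,
        metadata={
            "mode": mode,
            "config": config.as_dict(),
            "n_genes_fit": len(fits),
            "n_genes_skipped": len(skipped),
            "compute_accuracy": compute_accuracy,
            "feature_ids": {t: blk.feature_ids for t, blk in dataset.blocks.items()},
        },
    )


# ---------------------------------------------------------------------------
# Serialization: long coefficient table + per-gene summary + JSON manifest

LONG_COLUMNS = [
    "gene_id", "mode", "feature_id", "feature_type", "beta", "p_value",
    "lambda", "accuracy",
]


def results_to_frames(results: FitResults) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(long coefficient table, per-gene summary table)."""
    rows = []
    gene_rows = []
    for fit in results.fits.values():
        for t in BLOCK_ORDER:
            if t not in fit.beta:
                continue
            b = fit.beta[t]
            nz = np.flatnonzero(b)
            # feature ids live in the dataset; carried via metadata index
            for j in nz:
                rows.append(
                    (fit.gene_id, fit.mode, results.metadata["feature_ids"][t][j], t,
                     float(b[j]), float(fit.p_values[t][j]), fit.lam, fit.accuracy)
                )
        gene_rows.append(
            (fit.gene_id, fit.mode, fit.lam, fit.accuracy, fit.in_sample_accuracy,
             fit.n_selected, ";".join(fit.flags))
        )
    long = pd.DataFrame(rows, columns=LONG_COLUMNS)
    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "mode", "lambda", "accuracy", "in_sample_accuracy",
                 "n_selected", "flags"],
    )
    return long, genes


def save_results(results: FitResults, dataset: MultiOmicsDataset, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.metadata["feature_ids"] = {
        t: blk.feature_ids for t, blk in dataset.blocks.items()
    }
    long, genes = results_to_frames(results)
    tag = results.mode.replace(":", "_")
    long.to_csv(out / f"fits_{tag}.tsv", sep="\t", index=False, float_format="%.10g")
    genes.to_csv(out / f"genes_{tag}.tsv", sep="\t", index=False, float_format="%.10g")
    meta = {k: v for k, v in results.metadata.items() if k != "feature_ids"}
    meta["skipped"] = results.skipped
    (out / f"manifest_{tag}.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True)
    )
    return out
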