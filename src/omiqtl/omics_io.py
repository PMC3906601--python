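"""Loading, validation and preprocessing of multi-omics feature matrices.

The analysis consumes one feature matrix per genomic data type -- copy-number
alteration (CNA) as GISTIC cytoband calls in {-2, -1, 0, 1, 2}, DNA
methylation as beta-values in [0, 1], and miRNA expression as continuous
signals -- together with a gene-expression matrix whose rows become the
quantitative traits.  Files are tab-separated, features in rows and samples
in columns.  Preprocessing follows a fixed order: variance filtering on the
raw scale, sample alignment, then per-feature z-scoring (population
standard deviation, so that for a standardized column x'x = N exactly).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

CNA = "CNA"
METHYLATION = "methylation"
MIRNA = "miRNA"
FEATURE_TYPES = (CNA, METHYLATION, MIRNA)

CNA_CATEGORIES = frozenset({-2.0, -1.0, 0.0, 1.0, 2.0})

#: default lower-quantile variance cut per feature type; only methylation,
#: the largest feature set, is non-specifically filtered.
DEFAULT_VARIANCE_QUANTILE = {CNA: 0.0, METHYLATION: 0.25, MIRNA: 0.0}


class OmicsValidationError(ValueError):
    """Raised when an input matrix violates a structural invariant."""


def _check_unique(ids, what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise OmicsValidationError(
            f"duplicate {what}: {sorted(set(dups))}"
        )


@dataclass
class OmicsBlock:
    """One feature-type matrix: N samples x J features.

    ``values`` is sample-major (rows = samples) even though the on-disk
    convention is features x samples; loaders transpose.
    """

    type_label: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise OmicsValidationError(
                f"{self.type_label}: values shape {self.values.shape} does not "
                f"match {len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        _check_unique(self.feature_ids, f"{self.type_label} feature ids")
        _check_unique(self.sample_ids, f"{self.type_label} sample ids")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise OmicsValidationError(
                f"{self.type_label}: non-finite value at feature "
                f"'{self.feature_ids[bad[1]]}', sample '{self.sample_ids[bad[0]]}'"
            )
        if self.type_label == CNA and not self.normalized:
            bad_vals = set(np.unique(self.values)) - set(CNA_CATEGORIES)
            if bad_vals:
                raise OmicsValidationError(
                    f"CNA values must be in {{-2,-1,0,1,2}}; found {sorted(bad_vals)}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


@dataclass
class ExpressionTraits:
    """Gene-expression trait matrix (genes x samples) with per-gene mu/sigma.

    sigma uses the population convention (denominator N) to match feature
    standardization.  Genes with sigma == 0 carry no signal and are excluded
    from model fitting downstream.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    mu: np.ndarray = field(init=False)
    sigma: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise OmicsValidationError(
                f"expression: shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "expression sample ids")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise OmicsValidationError(
                f"expression: non-finite value at gene '{self.gene_ids[bad[0]]}', "
                f"sample '{self.sample_ids[bad[1]]}'"
            )
        self.mu = self.values.mean(axis=1)
        self.sigma = self.values.std(axis=1)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def zero_variance_genes(self) -> list[str]:
        return [g for g, s in zip(self.gene_ids, self.sigma) if s == 0.0]

    def trait(self, gene_id: str) -> np.ndarray:
        """The N-vector y_k for one gene."""
        return self.values[self.gene_ids.index(gene_id)]


@dataclass
class MultiOmicsDataset:
    """Aligned feature blocks plus expression traits sharing one sample order."""

    blocks: dict[str, OmicsBlock]
    expression: ExpressionTraits
    alignment_report: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise OmicsValidationError("dataset needs at least one feature block")
        ref = self.expression.sample_ids
        for label, blk in self.blocks.items():
            if blk.sample_ids != ref:
                raise OmicsValidationError(
                    f"block '{label}' sample order differs from expression"
                )

    @property
    def N(self) -> int:
        return self.expression.n_samples

    @property
    def M(self) -> int:
        return len(self.blocks)

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids


def _read_table(path) -> tuple[pd.DataFrame, list[str]]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    raw_samples = header[1:]
    raw = pd.read_csv(path, sep="\t", index_col=0)
    num = raw.apply(pd.to_numeric, errors="coerce")
    bad = num.isna().to_numpy() & raw.notna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise OmicsValidationError(
            f"{path.name}: non-numeric cell at row '{raw.index[r]}', "
            f"column '{raw.columns[c]}': {raw.iat[r, c]!r}"
        )
    if num.isna().to_numpy().any():
        r, c = np.argwhere(num.isna().to_numpy())[0]
        raise OmicsValidationError(
            f"{path.name}: missing value at row '{raw.index[r]}', "
            f"column '{raw.columns[c]}'"
        )
    return num, raw_samples


def read_feature_matrix(path, type_label: str) -> OmicsBlock:
    """Read a features x samples TSV into an (unnormalized) :class:`OmicsBlock`.

    First row holds sample ids, first column feature ids.  CNA matrices are
    validated against the categorical call set {-2,-1,0,1,2}.
    """
    if type_label not in FEATURE_TYPES:
        raise OmicsValidationError(
            f"unknown feature type '{type_label}'; expected one of {FEATURE_TYPES}"
        )
    num, raw_samples = _read_table(path)
    _check_unique(raw_samples, f"{Path(path).name} sample ids")
    return OmicsBlock(
        type_label=type_label,
        feature_ids=[str(x) for x in num.index],
        sample_ids=raw_samples,
        values=num.to_numpy(dtype=float).T,
    )


def read_expression_matrix(path) -> ExpressionTraits:
    """Read a genes x samples TSV into :class:`ExpressionTraits`."""
    num, raw_samples = _read_table(path)
    _check_unique(raw_samples, f"{Path(path).name} sample ids")
    return ExpressionTraits(
        gene_ids=[str(x) for x in num.index],
        sample_ids=raw_samples,
        values=num.to_numpy(dtype=float),
    )


def variance_filter(block: OmicsBlock, lower_quantile: float | None = None) -> OmicsBlock:
    """Drop features whose raw-scale variance falls strictly below the
    ``lower_quantile`` empirical quantile of per-feature variances.

    Defaults to 0.25 for methylation (the non-specific filter applied to the
    largest feature set) and 0 otherwise.  Must run before normalization:
    variances on the z-scored scale are all 1 and the filter would be
    meaningless.
    """
    if lower_quantile is None:
        lower_quantile = DEFAULT_VARIANCE_QUANTILE[block.type_label]
    if not (0.0 <= lower_quantile < 1.0):
        raise ValueError("lower_quantile must lie in [0, 1)")
    if block.normalized:
        raise OmicsValidationError(
            "variance_filter must be applied before z-score normalization"
        )
    if lower_quantile == 0.0:
        return block
    variances = block.values.var(axis=0)
    if np.all(variances == variances[0]):
        raise OmicsValidationError(
            f"{block.type_label}: all features have identical variance; "
            "a quantile variance filter would be arbitrary"
        )
    threshold = float(np.quantile(variances, lower_quantile))
    keep = variances >= threshold
    return OmicsBlock(
        type_label=block.type_label,
        feature_ids=[f for f, k in zip(block.feature_ids, keep) if k],
        sample_ids=block.sample_ids,
        values=block.values[:, keep],
    )


def zscore_normalize(block: OmicsBlock) -> OmicsBlock:
    """Standardize every feature to mean 0, population sd 1.

    Idempotent up to floating point.  Constant features are rejected by name:
    they must be removed (variance filter) before normalization.
    """
    mean = block.values.mean(axis=0)
    sd = block.values.std(axis=0)
    if np.any(sd == 0.0):
        j = int(np.argmax(sd == 0.0))
        raise OmicsValidationError(
            f"{block.type_label}: feature '{block.feature_ids[j]}' is constant "
            "and cannot be standardized; remove it first"
        )
    return replace(block, values=(block.values - mean) / sd, normalized=True)


def align_samples(
    blocks: list[OmicsBlock] | dict[str, OmicsBlock],
    expression: ExpressionTraits,
) -> MultiOmicsDataset:
    """Restrict all inputs to the sorted intersection of their sample ids.

    The result is invariant to the order in which blocks are supplied and to
    any sample permutation of an individual input.  Dropped samples are
    recorded per input in ``alignment_report``.
    """
    if isinstance(blocks, dict):
        blocks = list(blocks.values())
    if not blocks:
        raise OmicsValidationError("align_samples needs at least one block")
    labels = [b.type_label for b in blocks]
    _check_unique(labels, "block type labels")

    common = set(expression.sample_ids)
    for b in blocks:
        common &= set(b.sample_ids)
    if not common:
        raise OmicsValidationError("no sample id is shared by all inputs")
    order = sorted(common)

    report: dict[str, list[str]] = {}
    aligned: dict[str, OmicsBlock] = {}
    for b in sorted(blocks, key=lambda b: b.type_label):
        idx = [b.sample_ids.index(s) for s in order]
        report[b.type_label] = sorted(set(b.sample_ids) - common)
        aligned[b.type_label] = OmicsBlock(
            type_label=b.type_label,
            feature_ids=b.feature_ids,
            sample_ids=order,
            values=b.values[idx],
            normalized=b.normalized,
        )
    eidx = [expression.sample_ids.index(s) for s in order]
    report["expression"] = sorted(set(expression.sample_ids) - common)
    expr = ExpressionTraits(
        gene_ids=expression.gene_ids,
        sample_ids=order,
        values=expression.values[:, eidx],
    )
    return MultiOmicsDataset(blocks=aligned, expression=expr, alignment_report=report)


def preprocess(
    blocks: list[OmicsBlock],
    expression: ExpressionTraits,
    variance_quantiles: dict[str, float] | None = None,
) -> MultiOmicsDataset:
    """Full fixed-order pipeline: variance filter (raw scale) -> sample
    alignment -> z-score normalization.  Returns an analysis-ready dataset."""
    q = dict(DEFAULT_VARIANCE_QUANTILE)
    if variance_quantiles:
        q.update(variance_quantiles)
    filtered = [variance_filter(b, q[b.type_label]) for b in blocks]
    ds = align_samples(filtered, expression)
    normalized = {lab: zscore_normalize(b) for lab, b in ds.blocks.items()}
    return MultiOmicsDataset(
        blocks=normalized,
        expression=ds.expression,
        alignment_report=ds.alignment_report,
    )


# ---------------------------------------------------------------------------
# GISTIC converter

_GISTIC_META_COLS = (
    "Unique Name",
    "Descriptor",
    "Wide Peak Limits",
    "Peak Limits",
    "Region Limits",
    "q values",
    "Residual q values after removing segments shared with higher peaks",
    "Broad or Focal",
    "Amplitude Threshold",
)


def gistic_to_cna(path) -> OmicsBlock:
    """Convert a GISTIC ``all_lesions``-style table into a cytoband CNA block.

    Rows labelled 'Amplification Peak ...' / 'Deletion Peak ...' carrying the
    thresholded calls (not the '- CN values' rows) are kept; deletion calls
    are negated so the matrix lands in {-2,-1,0,1,2}.  The cytoband in the
    'Descriptor' column becomes the feature id (suffixed on collision).
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip() for c in df.columns]
    if "Unique Name" not in df.columns or "Descriptor" not in df.columns:
        raise OmicsValidationError(
            f"{Path(path).name}: not a GISTIC lesions table "
            "(missing 'Unique Name'/'Descriptor' columns)"
        )
    sample_cols = [
        c for c in df.columns
        if c not in _GISTIC_META_COLS and not c.startswith("Unnamed")
    ]
    mask = df["Unique Name"].str.contains("Peak") & ~df["Unique Name"].str.contains(
        "CN values"
    )
    df = df.loc[mask]
    feature_ids: list[str] = []
    rows: list[np.ndarray] = []
    seen: dict[str, int] = {}
    for _, row in df.iterrows():
        vals = pd.to_numeric(row[sample_cols], errors="raise").to_numpy(dtype=float)
        if row["Unique Name"].startswith("Deletion"):
            vals = -vals
        name = str(row["Descriptor"]).strip()
        if name in seen:
            seen[name] += 1
            name = f"{name}#{seen[name]}"
        else:
            seen[name] = 0
        feature_ids.append(name)
        rows.append(vals)
    return OmicsBlock(
        type_label=CNA,
        feature_ids=feature_ids,
        sample_ids=[str(c) for c in sample_cols],
        values=np.asarray(rows).T,
    )


# ---------------------------------------------------------------------------
# Dataset directory serialization

_BLOCK_FILES = {CNA: "cna.tsv", METHYLATION: "methylation.tsv", MIRNA: "mirna.tsv"}
EXPRESSION_FILE = "expression.tsv"
MANIFEST_FILE = "manifest.json"
FLOAT_FORMAT = "%.10g"


def _block_frame(block: OmicsBlock) -> pd.DataFrame:
    return pd.DataFrame(
        block.values.T, index=block.feature_ids, columns=block.sample_ids
    )


def write_dataset_dir(
    out_dir,
    blocks: list[OmicsBlock],
    expression: ExpressionTraits,
    params: dict | None = None,
) -> Path:
    """Serialize blocks + expression as a TSV directory with a JSON manifest
    (sample order, feature counts, parameters, content checksum)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = hashlib.sha256()
    files: dict[str, str] = {}
    for b in sorted(blocks, key=lambda b: b.type_label):
        fname = _BLOCK_FILES[b.type_label]
        text = _block_frame(b).to_csv(sep="\t", float_format=FLOAT_FORMAT)
        (out / fname).write_text(text)
        digest.update(text.encode())
        files[b.type_label] = fname
    etext = pd.DataFrame(
        expression.values, index=expression.gene_ids, columns=expression.sample_ids
    ).to_csv(sep="\t", float_format=FLOAT_FORMAT)
    (out / EXPRESSION_FILE).write_text(etext)
    digest.update(etext.encode())
    manifest = {
        "files": files,
        "expression_file": EXPRESSION_FILE,
        "sample_ids": expression.sample_ids,
        "n_samples": expression.n_samples,
        "n_genes": expression.n_genes,
        "feature_counts": {b.type_label: b.n_features for b in blocks},
        "normalized": {b.type_label: b.normalized for b in blocks},
        "params": params or {},
        "sha256": digest.hexdigest(),
    }
    (out / MANIFEST_FILE).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def read_dataset_dir(in_dir) -> tuple[list[OmicsBlock], ExpressionTraits, dict]:
    """Inverse of :func:`write_dataset_dir`; returns raw blocks, expression
    and the manifest."""
    d = Path(in_dir)
    manifest = json.loads((d / MANIFEST_FILE).read_text())
    blocks = [
        read_feature_matrix(d / fname, type_label)
        for type_label, fname in sorted(manifest["files"].items())
    ]
    expression = read_expression_matrix(d / manifest["expression_file"])
    return blocks, expression, manifest
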