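"""On-disk formats: per-subject time-series tables, phenotype CSVs, feature
matrices, evaluation reports and model checkpoints.

Conventions
-----------
* Time-series files are plain delimited text (TSV by default, CSV accepted),
  one subject per file, rows = timepoints, columns = ROIs.
* The phenotype table is a CSV with header ``subject_id,label,site_id``;
  labels are coded patient = 1, control = 0 so that downstream sigmoid
  outputs read as P(patient).
* Reports are JSON with a versioned schema; checkpoints are ``.npz``
  archives embedding the full model configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, RejectedSubjectError

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RoiTimeSeries:
    """One subject's T x n signal matrix (rows = timepoints, cols = ROIs)."""

    subject_id: str
    values: np.ndarray
    roi_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise FormatError(
                f"{self.subject_id}: time series must be a 2-D matrix")
        t, n = values.shape
        if t < 3:
            raise FormatError(f"{self.subject_id}: need at least 3 timepoints, got {t}")
        if n < 2:
            raise FormatError(f"{self.subject_id}: need at least 2 ROIs, got {n}")
        if not np.isfinite(values).all():
            raise RejectedSubjectError(
                f"{self.subject_id}: time series contains missing or "
                "non-finite values")
        if self.roi_labels is not None and len(self.roi_labels) != n:
            raise FormatError(
                f"{self.subject_id}: {len(self.roi_labels)} ROI labels for "
                f"{n} columns")
        object.__setattr__(self, "values", values)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True, eq=False)
class PhenotypeTable:
    """Cohort bookkeeping: subject ids, binary labels, site ids."""

    subject_ids: tuple[str, ...]
    labels: np.ndarray  # int array, patient=1 / control=0
    site_ids: tuple[str, ...]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhenotypeTable):
            return NotImplemented
        return (self.subject_ids == other.subject_ids
                and np.array_equal(self.labels, other.labels)
                and self.site_ids == other.site_ids)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.subject_ids) != len(labels) or len(labels) != len(self.site_ids):
            raise FormatError("phenotype columns have mismatched lengths")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            dupes = sorted({s for s in self.subject_ids
                            if list(self.subject_ids).count(s) > 1})
            raise FormatError(f"duplicate subject_id(s): {dupes[:5]}")
        bad = set(labels.tolist()) - {0, 1}
        if bad:
            raise FormatError(f"labels must be 0 or 1, found {sorted(bad)}")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.subject_ids)

    def label_of(self, subject_id: str) -> int:
        return int(self.labels[self.subject_ids.index(subject_id)])

    def site_of(self, subject_id: str) -> str:
        return self.site_ids[self.subject_ids.index(subject_id)]

    def subset(self, ids: list[str]) -> "PhenotypeTable":
        keep = set(ids)
        rows = [(s, l, g) for s, l, g in
                zip(self.subject_ids, self.labels, self.site_ids) if s in keep]
        return PhenotypeTable(tuple(r[0] for r in rows),
                              np.array([r[1] for r in rows], dtype=np.int64),
                              tuple(r[2] for r in rows))

    def require_both_classes(self) -> None:
        if len(set(self.labels.tolist())) < 2:
            raise FormatError("both classes required but only one present")


@dataclass
class Dataset:
    """A cohort: phenotypes plus per-subject series and optional features.

    Every phenotype row of an *input* cohort has a matching time series and
    all series share the same ROI count (T may vary).  Synthetic subjects
    created by augmentation exist only in feature space and carry no series;
    validation therefore tolerates feature-only subjects when
    ``allow_feature_only`` is set.
    """

    phenotypes: PhenotypeTable
    series: dict[str, RoiTimeSeries] = field(default_factory=dict)
    features: dict[str, np.ndarray] | None = None

    def validate(self, *, allow_feature_only: bool = False) -> None:
        n_rois = None
        for sid in self.phenotypes.subject_ids:
            ts = self.series.get(sid)
            if ts is None:
                if allow_feature_only and self.features and sid in self.features:
                    continue
                raise FormatError(f"subject {sid} has no time series")
            if n_rois is None:
                n_rois = ts.n_rois
            elif ts.n_rois != n_rois:
                raise FormatError(
                    f"subject {sid} has {ts.n_rois} ROIs, expected {n_rois}")

    @property
    def n_rois(self) -> int:
        ts = next(iter(self.series.values()))
        return ts.n_rois

    def feature_matrix(self, ids: list[str]) -> np.ndarray:
        if self.features is None:
            raise FormatError("dataset has no features")
        return np.stack([self.features[s] for s in ids])

    def labels_for(self, ids: list[str]) -> np.ndarray:
        lookup = dict(zip(self.phenotypes.subject_ids, self.phenotypes.labels))
        return np.array([lookup[s] for s in ids], dtype=np.int64)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_timeseries(path: str | Path, delimiter: str = "\t",
                    subject_id: str | None = None) -> RoiTimeSeries:
    """Read one subject's T x n time-series table from delimited text.

    Ragged rows raise :class:`FormatError`; any non-numeric or missing cell
    raises :class:`RejectedSubjectError` so the caller may skip the subject.
    """
    path = Path(path)
    sid = subject_id if subject_id is not None else path.stem
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            rows.append(line.split(delimiter))
    if not rows:
        raise FormatError(f"{path}: empty file")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise FormatError(f"{path}: rows of unequal length")
    try:
        values = np.array([[float(c) for c in r] for r in rows])
    except ValueError as exc:
        raise RejectedSubjectError(f"{sid}: non-numeric cell ({exc})") from exc
    return RoiTimeSeries(subject_id=sid, values=values)


def write_timeseries(ts: RoiTimeSeries, path: str | Path,
                     delimiter: str = "\t") -> None:
    np.savetxt(path, ts.values, delimiter=delimiter, fmt="%.10g")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read and validate the phenotype CSV (``subject_id,label,site_id``)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "site_id": str})
    required = {"subject_id", "label", "site_id"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    labels = df["label"].to_numpy()
    if not np.all(np.isin(labels, (0, 1))):
        raise FormatError(f"{path}: labels must be in {{0,1}}")
    return PhenotypeTable(tuple(df["subject_id"]),
                          labels.astype(np.int64),
                          tuple(df["site_id"].fillna("")))


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pd.DataFrame({
        "subject_id": pheno.subject_ids,
        "label": pheno.labels,
        "site_id": pheno.site_ids,
    }).to_csv(path, index=False)


def load_dataset(data_dir: str | Path, delimiter: str = "\t",
                 transpose: bool = False) -> Dataset:
    """Load phenotypes + per-subject series from a directory.

    Expects ``phenotypes.csv`` plus one ``<subject_id>.tsv`` per subject.
    Subjects whose series are missing cells are excluded (and logged),
    mirroring cohort-level quality control.
    """
    data_dir = Path(data_dir)
    pheno = read_phenotypes(data_dir / "phenotypes.csv")
    series: dict[str, RoiTimeSeries] = {}
    kept: list[str] = []
    for sid in pheno.subject_ids:
        path = data_dir / f"{sid}.tsv"
        try:
            ts = read_timeseries(path, delimiter=delimiter, subject_id=sid)
        except RejectedSubjectError as exc:
            logger.warning("excluding subject %s: %s", sid, exc)
            continue
        if transpose:
            ts = RoiTimeSeries(sid, ts.values.T)
        series[sid] = ts
        kept.append(sid)
    ds = Dataset(phenotypes=pheno.subset(kept), series=series)
    ds.validate()
    return ds


def save_dataset(ds: Dataset, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_phenotypes(ds.phenotypes, out_dir / "phenotypes.csv")
    for sid, ts in ds.series.items():
        write_timeseries(ts, out_dir / f"{sid}.tsv")


def write_features(features: dict[str, np.ndarray], path: str | Path) -> None:
    """Persist a subject x feature matrix as TSV with a subject_id column."""
    ids = list(features)
    mat = np.stack([features[s] for s in ids])
    df = pd.DataFrame(mat, index=pd.Index(ids, name="subject_id"))
    df.to_csv(path, sep="\t")


def read_features(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    return {str(sid): row.to_numpy(dtype=np.float64)
            for sid, row in df.iterrows()}


# ---------------------------------------------------------------------------
# evaluation reports
# ---------------------------------------------------------------------------

def write_report(report, path: str | Path) -> None:
    """Serialize an EvalReport to JSON (schema version 1)."""
    from .evaluation import EvalReport  # local import avoids a cycle

    if not isinstance(report, EvalReport):
        raise TypeError("write_report expects an EvalReport")
    if not report.folds:
        raise FormatError("refusing to write an empty report")
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": report.seed,
        "config": report.config,
        "folds": report.folds,
        "aggregate": report.aggregate,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)


def read_report(path: str | Path):
    from .evaluation import EvalReport

    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise FormatError(f"unsupported report schema: {doc.get('schema_version')}")
    return EvalReport(folds=doc["folds"], aggregate=doc["aggregate"],
                      config=doc["config"], seed=doc["seed"])


# ---------------------------------------------------------------------------
# model checkpoints (delegated to the model's own serialization)
# ---------------------------------------------------------------------------

def save_model(model, path: str | Path) -> None:
    """Save a model (SwnetModel or DAE) checkpoint with its config."""
    model.save(path)


def load_model(path: str | Path):
    """Load a checkpoint written by :func:`save_model`.

    Dispatches on the ``model_kind`` key stored in the archive.
    """
    from .dae import DenoisingAutoencoder
    from .swnet_classifier import SwnetModel

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path, allow_pickle=False) as npz:
        kind = str(npz["model_kind"])
    if kind == "swnet":
        return SwnetModel.load(path)
    if kind == "dae":
        return DenoisingAutoencoder.load(path)
    raise FormatError(f"unknown model kind {kind!r} in {path}")
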