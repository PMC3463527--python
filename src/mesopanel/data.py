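"""Core tabular data structures for aptamer-proteomic studies.

The central object is the :class:`RfuMatrix`, a samples x analytes table of
strictly positive Relative Fluorescence Units (RFU), accompanied by a
per-sample clinical/technical annotation table and a train/verify/validate
study split.  All interchange is plain TSV; missing values are illegal and
fail fast rather than being imputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CLASS_LABELS = frozenset({"CASE", "CONTROL", "CALIBRATOR", "BUFFER"})
DRAW_TYPES = frozenset({"PRE_OP", "INTRA_OP", "CLINIC", "NA"})
STAGES = frozenset({"I", "II", "III", "IV", "UNKNOWN", "NA"})
HISTOLOGIES = frozenset({"EPITHELIAL", "BIPHASIC", "SARCOMATOID", "UNKNOWN", "NA"})
ASSAY_VERSIONS = frozenset({"V1", "V2"})
KNOWN_SITES = frozenset({"NYU", "KAR", "LIB", "SIN"})
SYNTH_SITE_PREFIX = "SYNTH-"

ANNOTATION_COLUMNS = (
    "sample_id",
    "class_label",
    "site",
    "draw_type",
    "subject_id",
    "plate_id",
    "stage",
    "histology",
    "assay_version",
)

#: float format used for all written RFU values; round-trip identity is
#: guaranteed at this precision.
FLOAT_FMT = "%.6g"


class DataValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(ids: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise DataValidationError(f"duplicate {kind} ids: {sorted(set(dups))}")


@dataclasses.dataclass
class RfuMatrix:
    """Samples x analytes matrix of strictly positive RFU intensities.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with analyte ids as columns.  Every
        cell must be a finite float > 0; RFU are positive intensities and
        missing values are not representable.
    analyte_meta
        Optional per-analyte records (gene symbol, protein name, SwissProt
        id), indexed by analyte id.
    """

    values: pd.DataFrame
    analyte_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        _check_unique(v.index.astype(str), "sample")
        _check_unique(v.columns.astype(str), "analyte")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataValidationError("RFU matrix contains non-numeric cells")
        bad = ~np.isfinite(arr) | (arr <= 0)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise DataValidationError(
                f"non-positive or missing RFU at sample {v.index[r]!r}, "
                f"analyte {v.columns[c]!r} (value={arr[r, c]!r})"
            )
        self.values = v.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def log2(self) -> pd.DataFrame:
        """Matrix values on the log2 scale (the scale of all statistics)."""
        return np.log2(self.values)

    def subset(
        self,
        samples: Sequence[str] | None = None,
        analytes: Sequence[str] | None = None,
    ) -> "RfuMatrix":
        v = self.values
        if samples is not None:
            missing = set(samples) - set(v.index)
            if missing:
                raise KeyError(f"samples not in matrix: {sorted(missing)}")
            v = v.loc[list(samples)]
        if analytes is not None:
            missing = set(analytes) - set(v.columns)
            if missing:
                raise KeyError(f"analytes not in matrix: {sorted(missing)}")
            v = v[list(analytes)]
        meta = self.analyte_meta
        if meta is not None and analytes is not None:
            meta = meta.loc[[a for a in analytes if a in meta.index]]
        return RfuMatrix(v.copy(), meta)

    def canonical_sort(self) -> "RfuMatrix":
        """Return a copy with samples sorted lexicographically by id."""
        return RfuMatrix(self.values.sort_index(), self.analyte_meta)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update("\t".join(self.analyte_ids).encode())
        for sid, row in zip(self.sample_ids, self.values.to_numpy()):
            h.update(sid.encode())
            h.update(np.asarray(row).tobytes())
        return h.hexdigest()


def read_rfu_matrix(path: str | Path, layout: str = "samples_as_rows") -> RfuMatrix:
    """Read a TSV RFU matrix (header: ``sample_id<TAB>analyte...``).

    Raises :class:`DataValidationError` naming the offending cell for any
    duplicate id, ragged row, or non-positive/non-numeric value.
    """
    if layout != "samples_as_rows":
        raise ValueError(f"unsupported layout {layout!r}")
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise DataValidationError(f"{path}: empty file")
    header = lines[0].split("\t")
    analytes = header[1:]
    _check_unique(analytes, "analyte")
    sample_ids: list[str] = []
    rows: list[list[str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise DataValidationError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                f"expected {len(header)})"
            )
        sample_ids.append(fields[0])
        rows.append(fields[1:])
    _check_unique(sample_ids, "sample")
    raw = np.asarray(rows, dtype=object)
    try:
        arr = raw.astype(float)
    except ValueError:
        for (r, c), cell in np.ndenumerate(raw):
            try:
                float(cell)
            except ValueError:
                raise DataValidationError(
                    f"{path}: non-numeric value {cell!r} at sample "
                    f"{sample_ids[r]!r}, analyte {analytes[c]!r}"
                ) from None
        raise
    df = pd.DataFrame(arr, index=sample_ids, columns=analytes)
    return RfuMatrix(df)


def write_rfu_matrix(matrix: RfuMatrix, path: str | Path) -> None:
    """Write a TSV RFU matrix in canonical form (6 significant digits)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\t" + "\t".join(matrix.analyte_ids) + "\n")
        for sid, row in zip(matrix.sample_ids, matrix.values.to_numpy()):
            fh.write(sid + "\t" + "\t".join(FLOAT_FMT % x for x in row) + "\n")


def _validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"annotation missing required columns: {missing}")
    df = df.copy()
    for col in ANNOTATION_COLUMNS:
        df[col] = df[col].astype(str)
    _check_unique(df["sample_id"], "annotation sample")

    vocab = {
        "class_label": CLASS_LABELS,
        "draw_type": DRAW_TYPES,
        "stage": STAGES,
        "histology": HISTOLOGIES,
        "assay_version": ASSAY_VERSIONS,
    }
    for col, allowed in vocab.items():
        bad = sorted(set(df[col]) - allowed)
        if bad:
            raise DataValidationError(f"unknown {col} token(s): {bad}")
    bad_sites = sorted(
        s
        for s in set(df["site"])
        if s not in KNOWN_SITES and not s.startswith(SYNTH_SITE_PREFIX)
    )
    if bad_sites:
        raise DataValidationError(f"unknown site token(s): {bad_sites}")

    for _, row in df.iterrows():
        cl = row["class_label"]
        if cl == "CASE" and row["stage"] == "NA":
            raise DataValidationError(
                f"CASE sample {row['sample_id']!r} must carry a stage "
                "(UNKNOWN allowed, NA is not)"
            )
        if cl == "CONTROL" and row["stage"] != "NA":
            raise DataValidationError(
                f"CONTROL sample {row['sample_id']!r} must carry stage NA, "
                f"got {row['stage']!r}"
            )
        if cl in ("CALIBRATOR", "BUFFER") and (
            row["stage"] != "NA" or row["histology"] != "NA"
        ):
            raise DataValidationError(
                f"{cl} sample {row['sample_id']!r} must carry stage/histology NA"
            )
    return df.set_index("sample_id", drop=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample-annotation TSV.

    Returns a DataFrame indexed by ``sample_id`` with all annotation columns
    as strings, validated against the controlled vocabularies.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return _validate_annotation(df)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann[list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False)


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory annotation table (same rules as on read)."""
    return _validate_annotation(ann.reset_index(drop=True))


def check_matched(matrix: RfuMatrix, ann: pd.DataFrame) -> None:
    """Every matrix sample must have exactly one annotation row."""
    missing = set(matrix.sample_ids) - set(ann["sample_id"])
    if missing:
        raise DataValidationError(f"unannotated samples: {sorted(missing)}")


@dataclasses.dataclass(frozen=True)
class StudySplit:
    """Disjoint training / verification / validation sample-id sets."""

    training_ids: tuple[str, ...]
    verification_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        sets = [set(self.training_ids), set(self.verification_ids), set(self.validation_ids)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise DataValidationError("study split sets are not pairwise disjoint")

    def all_ids(self) -> set[str]:
        return set(self.training_ids) | set(self.verification_ids) | set(self.validation_ids)


def join_and_split(
    matrix: RfuMatrix,
    ann: pd.DataFrame,
    fraction: float = 0.75,
    seed: int = 0,
    validation_ids: Sequence[str] = (),
) -> StudySplit:
    """Stratified random split of the discovery cohort into train/verify.

    Calibrator and buffer wells are excluded from all splits.  Allocation is
    proportional by class with largest-remainder rounding; deterministic
    given ``seed``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    check_matched(matrix, ann)
    ann = ann.loc[ann["sample_id"].isin(matrix.sample_ids)]
    eligible = ann[ann["class_label"].isin(["CASE", "CONTROL"])]
    by_class = {
        cl: sorted(g["sample_id"]) for cl, g in eligible.groupby("class_label")
    }
    n_total = sum(len(v) for v in by_class.values())
    target = int(round(fraction * n_total))
    quotas = {cl: fraction * len(ids) for cl, ids in by_class.items()}
    base = {cl: int(np.floor(q)) for cl, q in quotas.items()}
    leftover = target - sum(base.values())
    # largest-remainder rounding; ties broken by class name for determinism
    order = sorted(quotas, key=lambda cl: (-(quotas[cl] - base[cl]), cl))
    for cl in order[: max(leftover, 0)]:
        base[cl] += 1
    rng = np.random.default_rng(seed)
    train: list[str] = []
    verify: list[str] = []
    for cl in sorted(by_class):
        ids = by_class[cl]
        k = min(base[cl], len(ids))
        chosen = rng.choice(len(ids), size=k, replace=False)
        chosen_set = {ids[i] for i in chosen}
        train.extend(i for i in ids if i in chosen_set)
        verify.extend(i for i in ids if i not in chosen_set)
    return StudySplit(tuple(train), tuple(verify), tuple(validation_ids), seed)


def write_split(split: StudySplit, path: str | Path) -> None:
    rows = (
        [(i, "training") for i in split.training_ids]
        + [(i, "verification") for i in split.verification_ids]
        + [(i, "validation") for i in split.validation_ids]
    )
    pd.DataFrame(rows, columns=["sample_id", "split"]).to_csv(path, sep="\t", index=False)


def read_split(path: str | Path, seed: int = 0) -> StudySplit:
    df = pd.read_csv(path, sep="\t", dtype=str)
    bad = sorted(set(df["split"]) - {"training", "verification", "validation"})
    if bad:
        raise DataValidationError(f"unknown split token(s): {bad}")
    by = {k: tuple(g["sample_id"]) for k, g in df.groupby("split")}
    return StudySplit(
        by.get("training", ()), by.get("verification", ()), by.get("validation", ()), seed
    )
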