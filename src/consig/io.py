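"""Reading and writing the pipeline's on-disk artifacts.

All tabular files are TSV, UTF-8, ``.`` decimal separator, empty string for
missing values — the dialect of GEO series-matrix exports without the SOFT
header machinery.  Probe IDs are case-sensitive; gene symbols are upper-cased
on ingest because symbol casing varies across annotation sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, LabelError, SizeError, StructuralError

CASE = "case"
CONTROL = "control"
UNMAPPED = "unmapped"

_VALID_CLASSES = {CASE, CONTROL}
_VALID_SUBTYPES = {"lesional", "non_lesional", "none"}


@dataclass
class ExpressionDataset:
    """One study's log2 expression matrix with per-sample labels.

    Parameters
    ----------
    dataset_id, platform_id
        Short identifiers for the study and its array platform.
    values
        Probes x samples matrix of log2 expression; NaN marks missing cells.
    sample_class
        Per-sample label, ``"case"`` or ``"control"``, indexed like the
        matrix columns.
    sample_subtype
        Optional per-sample biopsy subtype (``lesional``/``non_lesional``/
        ``none``).
    is_log2
        Whether values are already on the log2 scale.
    """

    dataset_id: str
    platform_id: str
    values: pd.DataFrame
    sample_class: pd.Series
    sample_subtype: pd.Series | None = None
    is_log2: bool = True

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise StructuralError(
                f"{self.dataset_id}: duplicate probe IDs in expression matrix"
            )
        if self.values.columns.has_duplicates:
            raise StructuralError(
                f"{self.dataset_id}: duplicate sample IDs in expression matrix"
            )
        matrix_samples = set(self.values.columns)
        label_samples = set(self.sample_class.index)
        if matrix_samples != label_samples:
            missing = matrix_samples ^ label_samples
            raise LabelError(
                f"{self.dataset_id}: samples do not match labels: {sorted(missing)!r}"
            )
        bad = set(self.sample_class) - _VALID_CLASSES
        if bad:
            raise LabelError(f"{self.dataset_id}: unknown class labels {sorted(bad)!r}")
        self.sample_class = self.sample_class.reindex(self.values.columns)
        if self.sample_subtype is not None:
            self.sample_subtype = self.sample_subtype.reindex(self.values.columns)
            bad = set(self.sample_subtype.dropna()) - _VALID_SUBTYPES
            if bad:
                raise LabelError(
                    f"{self.dataset_id}: unknown subtype labels {sorted(bad)!r}"
                )
        n_case = int((self.sample_class == CASE).sum())
        n_control = int((self.sample_class == CONTROL).sum())
        if n_case < 2 or n_control < 2:
            raise SizeError(
                f"{self.dataset_id}: need >= 2 samples per class, "
                f"got {n_case} case / {n_control} control"
            )
        if self.values.isna().all(axis=1).any():
            raise StructuralError(
                f"{self.dataset_id}: matrix contains entirely-missing probe rows"
            )

    @property
    def n_case(self) -> int:
        return int((self.sample_class == CASE).sum())

    @property
    def n_control(self) -> int:
        return int((self.sample_class == CONTROL).sum())

    def case_columns(self) -> list[str]:
        return list(self.sample_class.index[self.sample_class == CASE])

    def control_columns(self) -> list[str]:
        return list(self.sample_class.index[self.sample_class == CONTROL])


@dataclass
class ProbeAnnotation:
    """Probe -> gene-symbol mapping; unannotated probes map to ``unmapped``."""

    mapping: dict[str, str]

    def __post_init__(self):
        self.mapping = {
            str(probe): (str(sym).upper() if str(sym).strip() else UNMAPPED)
            for probe, sym in self.mapping.items()
        }

    def symbol(self, probe_id: str) -> str:
        return self.mapping.get(probe_id, UNMAPPED)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) for over-representation analysis."""

    sets: list[tuple[str, str, frozenset[str]]] = field(default_factory=list)

    def __post_init__(self):
        names = [name for name, _, _ in self.sets]
        if len(names) != len(set(names)):
            raise StructuralError("duplicate gene-set names in collection")
        for name, _, members in self.sets:
            if not members:
                raise StructuralError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_expression_matrix(
    path,
    labels_path,
    dataset_id: str = "dataset",
    platform_id: str = "platform",
) -> ExpressionDataset:
    """Load a TSV expression matrix plus its two/three-column label file.

    The matrix has a header row of sample IDs and probe IDs in the first
    column; blank cells become missing (NaN).  The labels file columns are
    ``sample_id``, ``class`` and optionally ``subtype``.
    """
    try:
        matrix = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse expression matrix {path}: {exc}") from exc
    if matrix.index.has_duplicates:
        raise StructuralError(f"{path}: duplicate probe IDs")
    if matrix.columns.has_duplicates:
        raise StructuralError(f"{path}: duplicate sample IDs")
    try:
        values = matrix.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric expression value: {exc}") from exc
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)

    labels = pd.read_csv(
        labels_path, sep="\t", header=None, dtype=str, skip_blank_lines=True
    )
    if labels.shape[1] < 2:
        raise FormatError(f"{labels_path}: expected >= 2 tab-separated columns")
    # Tolerate an optional header line.
    if str(labels.iloc[0, 0]).lower() in {"sample", "sample_id"}:
        labels = labels.iloc[1:]
    if labels[0].duplicated().any():
        raise LabelError(f"{labels_path}: duplicate sample IDs in labels")
    sample_class = pd.Series(
        labels[1].str.strip().values, index=labels[0].str.strip().values
    )
    subtype = None
    if labels.shape[1] >= 3 and labels[2].notna().any():
        subtype = pd.Series(labels[2].fillna("none").values, index=sample_class.index)
    return ExpressionDataset(
        dataset_id=dataset_id,
        platform_id=platform_id,
        values=values,
        sample_class=sample_class,
        sample_subtype=subtype,
    )


def write_expression_matrix(dataset: ExpressionDataset, path, labels_path) -> None:
    """Write a dataset back out in the same TSV dialect."""
    dataset.values.to_csv(path, sep="\t", na_rep="", float_format="%.10g")
    frame = pd.DataFrame(
        {"sample": dataset.sample_class.index, "class": dataset.sample_class.values}
    )
    if dataset.sample_subtype is not None:
        frame["subtype"] = dataset.sample_subtype.values
    frame.to_csv(labels_path, sep="\t", header=False, index=False)


def detect_log_scale(dataset: ExpressionDataset) -> bool:
    """True when values already look log2 (99th percentile strictly < 30)."""
    finite = dataset.values.to_numpy(dtype=float)
    finite = finite[np.isfinite(finite)]
    return bool(np.percentile(finite, 99) < 30)


def read_probe_annotation(path) -> ProbeAnnotation:
    """Two-column TSV probe_id -> gene_symbol; blank symbol = unmapped."""
    table = pd.read_csv(path, sep="\t", header=None, dtype=str).fillna("")
    if table.shape[1] < 2:
        raise FormatError(f"{path}: expected two tab-separated columns")
    if str(table.iloc[0, 0]).lower() in {"probe", "probe_id"}:
        table = table.iloc[1:]
    return ProbeAnnotation(dict(zip(table[0], table[1])))


def write_probe_annotation(annotation: ProbeAnnotation, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for probe, sym in annotation.mapping.items():
            fh.write(f"{probe}\t{sym}\n")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, then members."""
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc = fields[0], fields[1]
            members = frozenset(
                m.strip().upper() for m in fields[2:] if m.strip()
            )
            sets.append((name, desc, members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, desc, members in collection:
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


SIGNATURE_COLUMNS = [
    "gene",
    "direction",
    "cdr",
    "avg_log2fc",
    "avg_percent_rank",
    "n_datasets_measured",
    "min_p",
]


def write_signature_table(sig, path) -> None:
    """Write a signature as TSV, rows sorted by |avg_log2fc| descending."""
    frame = sig.to_frame()
    out = pd.DataFrame(
        {
            "gene": frame["gene_symbol"],
            "direction": frame["direction"],
            "cdr": frame["cdr"],
            "avg_log2fc": frame["avg_log2fc"],
            "avg_percent_rank": frame["avg_percent_rank"].round(3),
            "n_datasets_measured": frame["n_measured"],
            "min_p": frame["min_p"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_signature_table(path) -> pd.DataFrame:
    """Read a written signature TSV back into a DataFrame (same ordering)."""
    frame = pd.read_csv(path, sep="\t")
    missing = set(SIGNATURE_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing signature columns {sorted(missing)}")
    return frame
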