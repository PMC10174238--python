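"""Input/output layer: time-course datasets, cohort metadata, network labels, result tables.

All on-disk formats are tab-separated UTF-8 text with ``.`` as the decimal
mark.  A dataset is a manifest (``subject_id\tfile`` rows preceded by a
``# tr_seconds = <x>`` header line) pointing at one matrix file per subject,
rows = components, columns = timepoints.  Subject and component order is
manifest/file order everywhere downstream, which fixes pair indexing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DOMAINS = ("SC", "AUD", "VIS", "SM", "CC", "DM", "CB")
DIAGNOSES = ("HC", "SZ")
SEXES = ("M", "F")

#: significant digits used when writing floating-point table columns
FLOAT_DIGITS = 12


class ValidationError(ValueError):
    """Raised when an input file or table violates the documented contract."""


@dataclass
class TimecourseDataset:
    """Subjects x components x timepoints array of component time courses.

    ``data`` has shape ``(n_subjects, n_components, n_timepoints)`` in
    arbitrary BOLD-like units; ``tr_seconds`` is the sampling interval.
    """

    data: np.ndarray
    subject_ids: list[str]
    component_ids: list[str]
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(
                f"data must be 3-axis (subject, component, timepoint); got {self.data.ndim} axes"
            )
        if not np.isfinite(self.data).all():
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValidationError(
                f"non-finite value at subject {self.subject_ids[bad[0]]!r}, "
                f"component index {bad[1]}, timepoint {bad[2]}"
            )
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValidationError("subject_ids length does not match data")
        if len(self.component_ids) != self.data.shape[1]:
            raise ValidationError("component_ids length does not match data")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValidationError("duplicate subject ids")
        if len(set(self.component_ids)) != len(self.component_ids):
            raise ValidationError("duplicate component ids")
        if not self.tr_seconds > 0:
            raise ValidationError(f"tr_seconds must be positive, got {self.tr_seconds}")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]


@dataclass
class CohortMetadata:
    """Per-subject diagnosis (HC/SZ) and sex (M/F), aligned to dataset order."""

    table: pd.DataFrame  # columns: subject_id, diagnosis, sex

    def __post_init__(self) -> None:
        required = {"subject_id", "diagnosis", "sex"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        bad_dx = set(self.table["diagnosis"]) - set(DIAGNOSES)
        if bad_dx:
            raise ValidationError(f"unknown diagnosis levels: {sorted(bad_dx)} (expected HC/SZ)")
        bad_sex = set(self.table["sex"]) - set(SEXES)
        if bad_sex:
            raise ValidationError(f"unknown sex levels: {sorted(bad_sex)} (expected M/F)")
        if self.table["subject_id"].duplicated().any():
            dups = self.table.loc[self.table["subject_id"].duplicated(), "subject_id"]
            raise ValidationError(f"duplicate metadata rows for subjects: {sorted(set(dups))}")

    @property
    def diagnosis(self) -> np.ndarray:
        return self.table["diagnosis"].to_numpy()

    @property
    def sex(self) -> np.ndarray:
        return self.table["sex"].to_numpy()


@dataclass
class NetworkLabels:
    """Component id -> functional domain (one of the seven network domains)."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.mapping.values()) - set(DOMAINS)
        if bad:
            raise ValidationError(f"unknown network domains: {sorted(bad)} (expected {DOMAINS})")

    def domains_for(self, component_ids: list[str]) -> list[str]:
        missing = [c for c in component_ids if c not in self.mapping]
        if missing:
            raise ValidationError(f"components without a network label: {missing}")
        return [self.mapping[c] for c in component_ids]


# ---------------------------------------------------------------------------
# readers


def _read_manifest(manifest_path: str) -> tuple[float, list[tuple[str, str]]]:
    tr_seconds = None
    rows: list[tuple[str, str]] = []
    with open(manifest_path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    if key.strip() == "tr_seconds":
                        tr_seconds = float(val.strip())
                continue
            parts = line.split("\t")
            if parts[0] == "subject_id":  # header row
                continue
            if len(parts) != 2:
                raise ValidationError(f"manifest line not 'subject_id<TAB>file': {line!r}")
            rows.append((parts[0], parts[1]))
    if tr_seconds is None:
        raise ValidationError("manifest is missing a '# tr_seconds = <x>' header line")
    if not rows:
        raise ValidationError("manifest lists no subjects")
    return tr_seconds, rows


def load_dataset(manifest_path: str) -> TimecourseDataset:
    """Load a dataset from a manifest of per-subject matrix files.

    Each referenced file is a tab-separated matrix, rows = components,
    columns = timepoints.  All subjects must have identical shape; a ragged
    or missing file raises :class:`ValidationError` naming the subject.
    """
    tr_seconds, rows = _read_manifest(manifest_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    matrices = []
    shape = None
    for subject_id, rel in rows:
        path = rel if os.path.isabs(rel) else os.path.join(base, rel)
        if not os.path.exists(path):
            raise ValidationError(f"subject {subject_id!r}: file not found: {path}")
        try:
            mat = np.loadtxt(path, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise ValidationError(f"subject {subject_id!r}: unreadable matrix {path}: {exc}") from exc
        if not np.isfinite(mat).all():
            raise ValidationError(f"subject {subject_id!r}: non-finite values in {path}")
        if shape is None:
            shape = mat.shape
        elif mat.shape != shape:
            raise ValidationError(
                f"subject {subject_id!r}: matrix shape {mat.shape} differs from first subject {shape}"
            )
        matrices.append(mat)
    n_components = shape[0]
    component_ids = [f"comp{i + 1:03d}" for i in range(n_components)]
    return TimecourseDataset(
        data=np.stack(matrices),
        subject_ids=[s for s, _ in rows],
        component_ids=component_ids,
        tr_seconds=tr_seconds,
    )


def load_metadata(path: str, dataset: TimecourseDataset) -> CohortMetadata:
    """Load and validate the subject metadata table, reordered to dataset order."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    meta = CohortMetadata(table)
    have = set(meta.table["subject_id"])
    need = set(dataset.subject_ids)
    missing = sorted(need - have)
    if missing:
        raise ValidationError(f"metadata missing subjects present in dataset: {missing}")
    extra = sorted(have - need)
    if extra:
        raise ValidationError(f"metadata lists subjects absent from dataset: {extra}")
    ordered = meta.table.set_index("subject_id").loc[dataset.subject_ids].reset_index()
    return CohortMetadata(ordered)


def load_network_labels(path: str, dataset: TimecourseDataset | None = None) -> NetworkLabels:
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"component_id", "domain"}
    if required - set(table.columns):
        raise ValidationError("network label table needs columns component_id, domain")
    labels = NetworkLabels(dict(zip(table["component_id"], table["domain"])))
    if dataset is not None:
        labels.domains_for(dataset.component_ids)
    return labels


# ---------------------------------------------------------------------------
# writers


def _format_value(v) -> str:
    if isinstance(v, (float, np.floating)):
        return f"{v:.{FLOAT_DIGITS}g}"
    if isinstance(v, (np.integer,)):
        return str(int(v))
    return str(v)


def write_table(rows: pd.DataFrame, path: str, sort_keys: list[str] | None = None) -> None:
    """Write a result table as TSV with a deterministic row order.

    Floats are written with 12 significant digits, which round-trips the
    values to better than 1e-9 relative error.  If ``sort_keys`` is given the
    rows are sorted by those columns before writing.
    """
    df = rows.copy()
    if sort_keys:
        df = df.sort_values(sort_keys, kind="mergesort").reset_index(drop=True)
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_format_value(v) for v in row) + "\n")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(mat: np.ndarray, ids: list[str], path: str, header_lines: list[str] | None = None) -> None:
    """Write a labelled square matrix (component ids as header and row names)."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("\t" + "\t".join(ids) + "\n")
        for rid, row in zip(ids, np.asarray(mat)):
            fh.write(rid + "\t" + "\t".join(f"{v:.{FLOAT_DIGITS}g}" for v in row) + "\n")


def read_matrix(path: str) -> tuple[np.ndarray, list[str]]:
    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    ids = lines[0].rstrip("\n").split("\t")[1:]
    mat = np.array([[float(x) for x in ln.rstrip("\n").split("\t")[1:]] for ln in lines[1:]])
    return mat, ids


def write_dataset(dataset: TimecourseDataset, out_dir: str) -> str:
    """Persist a dataset in the manifest layout; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        fh.write(f"# tr_seconds = {dataset.tr_seconds:.12g}\n")
        fh.write("subject_id\tfile\n")
        for s, mat in zip(dataset.subject_ids, dataset.data):
            rel = f"{s}.tsv"
            np.savetxt(os.path.join(out_dir, rel), mat, delimiter="\t", fmt=f"%.{FLOAT_DIGITS}g")
            fh.write(f"{s}\t{rel}\n")
    return manifest_path


def write_metadata(metadata: CohortMetadata, path: str) -> None:
    write_table(metadata.table, path)


def write_network_labels(labels: NetworkLabels, path: str) -> None:
    df = pd.DataFrame(
        {"component_id": list(labels.mapping), "domain": list(labels.mapping.values())}
    )
    write_table(df, path)
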