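"""File formats: connectome TSV, subject manifests, NIfTI volumes, streamlines.

All tabular output is tab-delimited UTF-8 with Unix newlines and ``%.6g``
float formatting so identical runs serialize byte-identically. Matrix files
may begin with ``#``-prefixed echo lines recording the parameters that
produced them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import SubjectRecord
from .tracto import (
    Connectome,
    DirectionVolume,
    Parcellation,
    ScalarVolume,
    StreamlineSet,
    build_connectome,
)

__all__ = [
    "write_connectome_tsv",
    "read_connectome_tsv",
    "write_manifest_tsv",
    "read_manifest_tsv",
    "write_matrix_tsv",
    "save_scalar_volume",
    "load_scalar_volume",
    "save_direction_volume",
    "load_direction_volume",
    "save_parcellation",
    "load_parcellation",
    "write_streamlines_jsonl",
    "read_streamlines_jsonl",
    "write_cohort",
    "read_cohort",
]


def _fmt(v: float | int) -> str:
    if float(v).is_integer():
        return str(int(v))
    return format(float(v), ".6g")


def _echo_lines(echo: Mapping[str, object] | None) -> list[str]:
    if not echo:
        return []
    return [f"# {k}={v}" for k, v in echo.items()]


def write_matrix_tsv(
    path: str | Path,
    matrix: np.ndarray,
    labels: Sequence[str],
    echo: Mapping[str, object] | None = None,
) -> None:
    """Write a labeled square matrix as TSV (optional ``#`` parameter echo)."""
    matrix = np.asarray(matrix)
    lines = _echo_lines(echo)
    lines.append("\t".join(labels))
    for row in matrix:
        lines.append("\t".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    rows: list[list[str]] = []
    header: list[str] | None = None
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        rows.append(fields)
    if header is None or not rows:
        raise ValueError(f"{path}: empty matrix file")
    n = len(header)
    if len(rows) != n or any(len(r) != n for r in rows):
        raise ValueError(f"{path}: ragged matrix ({len(rows)} rows for {n} columns)")
    try:
        mat = np.array([[float(v) for v in r] for r in rows])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    return mat, header


def write_connectome_tsv(
    path: str | Path, connectome: Connectome, echo: Mapping[str, object] | None = None
) -> None:
    full_echo = {"fiber_threshold": connectome.fiber_threshold, **(echo or {})}
    write_matrix_tsv(path, connectome.counts, connectome.labels, full_echo)


def read_connectome_tsv(path: str | Path, fiber_threshold: int = 3) -> Connectome:
    """Read a count matrix; the adjacency is recomputed from the threshold.

    Asymmetry is a hard error naming the offending cell (tolerance 0).
    """
    mat, labels = _read_matrix_tsv(path)
    asym = np.argwhere(mat != mat.T)
    if asym.size:
        i, j = asym[0]
        raise ValueError(
            f"{path}: asymmetric counts at cell ({labels[i]}, {labels[j]}): "
            f"{mat[i, j]} != {mat[j, i]}"
        )
    if np.any(mat != np.rint(mat)):
        raise ValueError(f"{path}: counts must be integers")
    return build_connectome(
        mat.astype(int), fiber_threshold=fiber_threshold, labels=labels
    )


def write_manifest_tsv(path: str | Path, manifest: pd.DataFrame) -> None:
    out = manifest.copy()
    for c in ("age", "education"):
        if c in out:
            out[c] = out[c].map(_fmt)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_manifest_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "group", "age", "sex", "education"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


def save_scalar_volume(path: str | Path, vol: ScalarVolume) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.voxel_size))
    nib.save(img, str(path))


def load_scalar_volume(path: str | Path) -> ScalarVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: scalar volume must be 3-D, got {data.ndim}-D")
    voxel_size = float(img.header.get_zooms()[0])
    return ScalarVolume(data=data, voxel_size=voxel_size)  # validates FA range


def save_direction_volume(path: str | Path, vol: DirectionVolume) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float64), _affine(1.0))
    nib.save(img, str(path))


def load_direction_volume(path: str | Path) -> DirectionVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path}: direction volume must be 4-D with last dim 3")
    return DirectionVolume(data=data)


def save_parcellation(path: str | Path, parc: Parcellation) -> None:
    img = nib.Nifti1Image(parc.labels.astype(np.int32), _affine(1.0))
    img.header.set_intent("label")
    nib.save(img, str(path))
    if parc.region_names:
        Path(str(path) + ".labels.json").write_text(
            json.dumps(list(parc.region_names)), encoding="utf-8"
        )


def load_parcellation(path: str | Path) -> Parcellation:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: parcellation must be 3-D")
    if not np.issubdtype(data.dtype, np.integer):
        if np.any(data != np.rint(data)):
            raise ValueError(f"{path}: parcellation labels must be integers")
        data = data.astype(np.int32)
    names: tuple[str, ...] = ()
    label_file = Path(str(path) + ".labels.json")
    if label_file.exists():
        names = tuple(json.loads(label_file.read_text(encoding="utf-8")))
    return Parcellation(labels=data, region_names=names)


# ---------------------------------------------------------------------------
# streamlines (JSON lines: one polyline per line)
# ---------------------------------------------------------------------------


def write_streamlines_jsonl(path: str | Path, s: StreamlineSet) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"step_size": s.step_size}) + "\n")
        for poly, reasons in zip(s.streamlines, s.reasons):
            fh.write(
                json.dumps({"points": poly.tolist(), "reasons": list(reasons)}) + "\n"
            )


def read_streamlines_jsonl(path: str | Path) -> StreamlineSet:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}: empty streamline file")
    meta = json.loads(lines[0])
    out = StreamlineSet(step_size=float(meta["step_size"]))
    for line in lines[1:]:
        rec = json.loads(line)
        out.streamlines.append(np.asarray(rec["points"], dtype=float))
        out.reasons.append(tuple(rec["reasons"]))
    return out


# ---------------------------------------------------------------------------
# cohort bundles
# ---------------------------------------------------------------------------


def write_cohort(
    directory: str | Path,
    subjects: Sequence[SubjectRecord],
    labels: Sequence[str],
    ground_truth=None,
    fiber_threshold: int = 3,
) -> None:
    """Write manifest + per-subject count TSVs (+ ground truth JSON)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    from .cohort import manifest_frame

    write_manifest_tsv(directory / "manifest.tsv", manifest_frame(subjects))
    counts_dir = directory / "counts"
    counts_dir.mkdir(exist_ok=True)
    for s in subjects:
        conn = build_connectome(s.counts, fiber_threshold, labels)
        write_connectome_tsv(counts_dir / f"{s.subject_id}.tsv", conn)
    if ground_truth is not None:
        gt = {
            "perturbed_edges": {
                g: [[i, j, f] for i, j, f in edges]
                for g, edges in ground_truth.perturbed_edges.items()
            },
            "nodal_bc_targets": {
                g: list(t) for g, t in ground_truth.nodal_bc_targets.items()
            },
        }
        (directory / "ground_truth.json").write_text(
            json.dumps(gt, indent=1), encoding="utf-8"
        )


def read_cohort(
    directory: str | Path, fiber_threshold: int = 3
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Read a cohort bundle back; returns subjects and the manifest."""
    directory = Path(directory)
    manifest = read_manifest_tsv(directory / "manifest.tsv")
    subjects = []
    for _, row in manifest.iterrows():
        conn = read_connectome_tsv(
            directory / "counts" / f"{row.subject_id}.tsv", fiber_threshold
        )
        subjects.append(
            SubjectRecord(
                subject_id=row.subject_id,
                group=row.group,
                age=float(row.age),
                sex=row.sex,
                education=float(row.education),
                counts=conn.counts,
            )
        )
    return subjects, manifest
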