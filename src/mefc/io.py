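"""NIfTI-1 / TSV input and output.

All volumes travel as NIfTI-1 (RAS+, mm, time axis last) via nibabel;
tables (motion parameters, label tables, correlation matrices, reports) as
tab-separated text.  Multi-echo series get a JSON sidecar recording echo
times and TR.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import BoldSeries, MultiEchoSeries, Parcellation

__all__ = [
    "save_volume", "load_volume",
    "save_bold", "load_bold",
    "save_multi_echo", "load_multi_echo",
    "save_parcellation", "load_parcellation",
    "read_label_table", "write_label_table",
    "write_matrix_tsv", "read_matrix_tsv",
]


def save_volume(path: str | Path, data: np.ndarray, affine: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_bold(path: str | Path, b: BoldSeries) -> Path:
    """4D series plus a `<stem>_sidecar.json` with TR and the df ledger."""
    path = Path(path)
    save_volume(path, b.data, b.affine)
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({
        "tr_ms": b.tr_ms,
        "df_ledger": [[e.stage, e.n_removed, e.counted] for e in b.df_ledger],
    }, indent=1))
    save_volume(path.parent / (_stem(path) + "_mask.nii.gz"), b.mask, b.affine)
    return path


def load_bold(path: str | Path) -> BoldSeries:
    from .types import DfEntry

    path = Path(path)
    data, affine = load_volume(path)
    meta = json.loads(_sidecar_path(path).read_text())
    mask, _ = load_volume(path.parent / (_stem(path) + "_mask.nii.gz"))
    ledger = [DfEntry(s, int(n), bool(c)) for s, n, c in meta.get("df_ledger", [])]
    return BoldSeries(data=np.asarray(data, dtype=float), tr_ms=meta["tr_ms"],
                      mask=mask.astype(bool), affine=affine, df_ledger=ledger)


def _stem(path: Path) -> str:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return path.stem


def _sidecar_path(path: Path) -> Path:
    return path.parent / (_stem(path) + "_sidecar.json")


def save_multi_echo(directory: str | Path, me: MultiEchoSeries, stem: str) -> list[Path]:
    """Write one 4D NIfTI per echo (`<stem>_echo<k>.nii.gz`, 1-based) plus a
    JSON sidecar with te_ms and tr_ms and the brain mask."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, arr in enumerate(me.data, start=1):
        paths.append(save_volume(directory / f"{stem}_echo{k}.nii.gz", arr, me.affine))
    (directory / f"{stem}_sidecar.json").write_text(
        json.dumps({"te_ms": list(me.te_ms), "tr_ms": me.tr_ms}, indent=1))
    save_volume(directory / f"{stem}_mask.nii.gz", me.mask, me.affine)
    return paths


def load_multi_echo(directory: str | Path, stem: str) -> MultiEchoSeries:
    directory = Path(directory)
    meta = json.loads((directory / f"{stem}_sidecar.json").read_text())
    te_ms = meta["te_ms"]
    data = []
    affine = None
    for k in range(1, len(te_ms) + 1):
        arr, affine = load_volume(directory / f"{stem}_echo{k}.nii.gz")
        data.append(np.asarray(arr, dtype=float))
    mask, _ = load_volume(directory / f"{stem}_mask.nii.gz")
    return MultiEchoSeries(data=data, te_ms=tuple(te_ms), tr_ms=meta["tr_ms"],
                           mask=mask.astype(bool), affine=affine)


def save_parcellation(directory: str | Path, p: Parcellation, stem: str = "parc") -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = save_volume(directory / f"{stem}.nii.gz",
                       p.labels.astype(np.int32), p.affine)
    write_label_table(directory / f"{stem}_labels.tsv", p.table)
    return path


def load_parcellation(directory: str | Path, stem: str = "parc") -> Parcellation:
    directory = Path(directory)
    labels, affine = load_volume(directory / f"{stem}.nii.gz")
    table = read_label_table(directory / f"{stem}_labels.tsv")
    return Parcellation(labels=np.asarray(labels).astype(np.int32),
                        table=table, affine=affine)


def write_label_table(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_label_table(path: str | Path) -> pd.DataFrame:
    """Validated label table: TSV with columns label, name, class; integer
    unique labels required."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    if table.empty:
        raise ValueError(f"label table {path} is empty")
    required = {"label", "name", "class"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"label table {path} missing columns {sorted(missing)}")
    if not pd.api.types.is_integer_dtype(table["label"]):
        raise ValueError(f"label column of {path} must be integer")
    dupes = table.loc[table["label"].duplicated(), "label"]
    if len(dupes):
        raise ValueError(f"duplicate label(s) in {path}: {sorted(set(dupes))}")
    return table


def write_matrix_tsv(path: str | Path, r: np.ndarray, names: list) -> Path:
    """Square matrix as TSV with a header row and index column of names."""
    path = Path(path)
    pd.DataFrame(r, index=names, columns=names).to_csv(path, sep="\t")
    return path


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]
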