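"""Matrix and montage I/O: TSV with '#' comment headers, plus a named-array
binary container (NumPy ``.npz``) for trial archives."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_matrix_tsv(path, matrix, comments=()) -> None:
    """Row-major TSV; every comment line is prefixed with '# '."""
    header = "\n".join(str(c) for c in comments)
    np.savetxt(path, np.atleast_2d(np.asarray(matrix, dtype=float)),
               delimiter="\t", header=header, comments="# ")


def read_matrix_tsv(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t", comments="#"))


def write_montage_tsv(path, labels, positions) -> None:
    """Sensor montage: one row per sensor, ``label<TAB>x<TAB>y<TAB>z`` in mm."""
    positions = np.asarray(positions, dtype=float)
    with open(path, "w") as fh:
        fh.write("# label\tx_mm\ty_mm\tz_mm\n")
        for lab, (x, y, z) in zip(labels, positions):
            fh.write(f"{lab}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def read_montage_tsv(path):
    labels, rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
    return labels, np.asarray(rows)


def write_container(path, **arrays) -> None:
    """Named-array binary container (uncompressed ``.npz``)."""
    np.savez(path, **arrays)


def read_container(path) -> dict:
    with np.load(path, allow_pickle=False) as data:
        return {k: data[k] for k in data.files}


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
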