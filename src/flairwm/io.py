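"""Volume and manifest I/O.

Volumes are 3D scalar grids in NIfTI-1 files; the third canonical axis is the
slice axis (the one the 2D/3D acquisition rules refer to). Scan manifests are
CSV files with the mandatory header ``scan_id,path,label,protocol_id,dataset_id``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

POSITIVE = "positive"
NEGATIVE = "negative"
LABELS = (POSITIVE, NEGATIVE)

MANIFEST_COLUMNS = ["scan_id", "path", "label", "protocol_id", "dataset_id"]


@dataclasses.dataclass
class Volume:
    """A 3D image grid with per-axis voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        """Slice count along the third (slice) axis."""
        return self.data.shape[2]


@dataclasses.dataclass(frozen=True)
class ManifestEntry:
    scan_id: str
    path: str
    label: str
    protocol_id: str
    dataset_id: str


@dataclasses.dataclass
class ScanManifest:
    """An ordered collection of scans with class labels and protocol/dataset ids."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        ids = [e.scan_id for e in self.entries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate scan_id(s): {sorted(dupes)}")
        bad = {e.label for e in self.entries} - set(LABELS)
        if bad:
            raise ValueError(f"unknown label token(s): {sorted(bad)}; expected {LABELS}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def class_counts(self) -> dict[str, int]:
        counts = {lab: 0 for lab in LABELS}
        for e in self.entries:
            counts[e.label] += 1
        return counts

    def protocols(self) -> list[str]:
        """Distinct protocol ids in first-appearance order."""
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.protocol_id, None)
        return list(seen)

    def datasets(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.dataset_id, None)
        return list(seen)

    def subset(self, scan_ids: Iterable[str]) -> "ScanManifest":
        wanted = set(scan_ids)
        return ScanManifest([e for e in self.entries if e.scan_id in wanted])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(e) for e in self.entries],
                            columns=MANIFEST_COLUMNS)


def read_volume(path: str | Path) -> Volume:
    """Read a single-channel 3D NIfTI-1 image.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        For non-3D data or images carrying neither a qform nor an sform
        orientation (some clinical exports lack both, which makes the
        physical orientation of the brain ambiguous).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[-1] == 1 else data
    if data.ndim != 3:
        raise ValueError(f"expected 3D image, got {data.ndim}D in {path}")
    hdr = img.header
    if int(hdr["qform_code"]) == 0 and int(hdr["sform_code"]) == 0:
        raise ValueError(
            f"{path}: missing orientation metadata (both qform and sform codes are 0)"
        )
    spacing = tuple(float(z) for z in hdr.get_zooms()[:3])
    return Volume(np.asarray(data, dtype=np.float64), spacing)


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a Volume as NIfTI-1; spacing is stored on the affine diagonal."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float64), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def load_manifest(path: str | Path) -> ScanManifest:
    """Load a CSV scan manifest (header row mandatory)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing column(s): {missing}")
    entries = [
        ManifestEntry(r.scan_id, r.path, r.label, r.protocol_id, r.dataset_id)
        for r in df.itertuples(index=False)
    ]
    return ScanManifest(entries)


def save_manifest(manifest: ScanManifest, path: str | Path) -> None:
    manifest.to_frame().to_csv(path, index=False)


def child_seed(master: int, *keys: int | str) -> int:
    """Derive a deterministic child seed (< 2**31) from a master seed and keys.

    Every source of randomness in the package draws from seeds produced here,
    so one top-level seed reproduces the full shuffle/run/scan grid.
    """
    ints = [int(master) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            h = 2166136261
            for ch in k.encode():
                h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
            ints.append(h)
        else:
            ints.append(int(k) & 0xFFFFFFFF)
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def rng_from(master: int, *keys: int | str) -> np.random.Generator:
    return np.random.default_rng(child_seed(master, *keys))
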