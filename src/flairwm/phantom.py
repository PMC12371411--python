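"""Synthetic FLAIR-like brain phantoms.

The generator emulates, at desk scale, the inputs the classification pipeline
sees in practice: bias-corrected FLAIR volumes already aligned to a common
template space, together with the template's white-matter probability map.
A phantom head is a set of nested ellipsoids — a CSF core standing in for the
ventricles, a white-matter shell, and a gray-matter rim — with FLAIR-like
contrast (dark CSF, mid WM, brighter GM) and, in positive cases, hyperintense
blob lesions inside the WM. Per-protocol heterogeneity is purely
non-biological: an affine intensity transform, a smooth multiplicative bias
field, additive Gaussian noise, and optional thick-slice (2D-acquisition)
emulation along the slice axis.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import (NEGATIVE, POSITIVE, ManifestEntry, ScanManifest, Volume,
                 rng_from, save_manifest, write_volume)

# FLAIR-like tissue intensity levels (arbitrary units). Only the ordering
# CSF < WM < GM < lesion carries meaning downstream.
CSF_LEVEL = 0.1
WM_LEVEL = 0.5
GM_LEVEL = 0.65


@dataclasses.dataclass
class TissueTemplate:
    """Smooth tissue probability maps for the three compartments."""

    wm_prob: np.ndarray
    gm_prob: np.ndarray
    csf_prob: np.ndarray

    def __post_init__(self) -> None:
        for name in ("wm_prob", "gm_prob", "csf_prob"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
                raise ValueError(f"{name} outside [0,1]")
            setattr(self, name, np.clip(arr, 0.0, 1.0))
        total = self.wm_prob + self.gm_prob + self.csf_prob
        if total.max() > 1 + 1e-6:
            raise ValueError("tissue probabilities sum above 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.wm_prob.shape


@dataclasses.dataclass(frozen=True)
class ProtocolSpec:
    """One simulated acquisition protocol.

    ``bias_amplitude`` is the peak-to-peak fraction of the smooth
    multiplicative field (0.2 means the field spans roughly 0.9–1.1);
    ``lesion_contrast`` is the lesion / normal-WM mean intensity ratio;
    ``n_slices`` below the template slice count emulates a thick-slice 2D
    acquisition resampled back to template space.
    """

    protocol_id: str
    gain: float = 1.0
    offset: float = 0.0
    noise_sd: float = 0.0
    bias_amplitude: float = 0.0
    n_slices: int = 10**9
    lesion_contrast: float = 1.6

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.noise_sd < 0 or self.bias_amplitude < 0:
            raise ValueError("noise_sd and bias_amplitude must be >= 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.lesion_contrast <= 1:
            raise ValueError("lesion_contrast must be > 1")


@dataclasses.dataclass
class PhantomSample:
    image: Volume
    label: str
    lesion_mask: np.ndarray
    protocol_id: str
    truth_tissue: TissueTemplate
    clean_image: np.ndarray | None = None  # noise-free, pre-protocol image

    def __post_init__(self) -> None:
        has_lesion = bool(np.any(self.lesion_mask))
        if (self.label == POSITIVE) != has_lesion:
            raise ValueError("label/lesion_mask mismatch")


def generate_template(shape: Sequence[int], seed: int) -> TissueTemplate:
    """Build a head-like tissue template: CSF core, WM shell, GM rim.

    Hard compartment labels on nested ellipsoids are Gaussian-blurred into
    smooth probability maps; the blur preserves the partition of unity, so
    the three maps sum to at most 1 (less than 1 where brain meets
    background). Deterministic given (shape, seed): the seed only perturbs
    the ellipsoid axes slightly so different templates are distinguishable.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 16 for s in shape):
        raise ValueError(f"template shape must be 3 dims each >= 16, got {shape}")
    rng = rng_from(seed, "template")
    center = [(s - 1) / 2.0 for s in shape]
    semi = np.array([0.42 * s for s in shape]) * rng.uniform(0.97, 1.03, size=3)
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    r = np.sqrt(sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi)))

    csf = (r < 0.28).astype(np.float64)          # ventricle-like core
    wm = ((r >= 0.28) & (r < 0.72)).astype(np.float64)
    gm = ((r >= 0.72) & (r < 0.95)).astype(np.float64)

    sigma = max(min(shape) / 40.0, 0.6)
    csf = ndimage.gaussian_filter(csf, sigma)
    wm = ndimage.gaussian_filter(wm, sigma)
    gm = ndimage.gaussian_filter(gm, sigma)
    return TissueTemplate(wm_prob=wm, gm_prob=gm, csf_prob=csf)


#: Standard deviation of the smooth within-WM intensity texture (fraction of
#: the WM level). Real white matter is not uniformly bright on FLAIR —
#: myelination and tract geometry produce smooth regional variation — and
#: this biological texture is what makes the brightest intensity cluster
#: diffuse in healthy brains versus lesion-concentrated in abnormal ones.
WM_TEXTURE_SD = 0.08


def _wm_texture(shape: tuple[int, int, int], rng: np.random.Generator,
                texture_sd: float = WM_TEXTURE_SD) -> np.ndarray:
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=min(shape) / 10.0)
    sd = tex.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return np.clip(tex / sd * texture_sd, -0.25, 0.25)


def _bias_field(shape: tuple[int, int, int], amplitude: float,
                rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field with the requested peak-to-peak span."""
    if amplitude == 0:
        return np.ones(shape)
    coarse = rng.standard_normal([max(s // 8, 2) for s in shape])
    zoom = [s / c for s, c in zip(shape, coarse.shape)]
    field = ndimage.zoom(coarse, zoom, order=3)[: shape[0], : shape[1], : shape[2]]
    field = ndimage.gaussian_filter(field, sigma=min(shape) / 8.0)
    span = field.max() - field.min()
    if span < 1e-12:
        return np.ones(shape)
    field = (field - field.min()) / span - 0.5       # [-0.5, 0.5]
    return 1.0 + amplitude * field


def _place_lesions(template: TissueTemplate, contrast: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Return (additive lesion signal, binary lesion mask) inside the WM core.

    1-3 smooth-edged blobs whose radii scale with the head size, giving
    lesion loads of roughly 3-10% of the WM core — the multifocal-to-
    confluent regime typical of demyelinating disease.
    """
    wm_core = template.wm_prob >= 0.5
    if wm_core.sum() < 30:
        raise ValueError("WM region too small to host a lesion")
    coords = np.argwhere(wm_core)
    shape = template.shape
    n_blobs = int(rng.integers(1, 4))
    profile = np.zeros(shape)
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    r_lo = 2.5
    r_hi = max(min(shape) / 5.0, r_lo + 0.1)
    for _ in range(n_blobs):
        c = coords[rng.integers(len(coords))]
        radius = rng.uniform(r_lo, r_hi)
        d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        profile = np.maximum(profile, np.exp(-0.5 * d2 / (radius / 1.7) ** 2))
    mask = (profile >= 0.5) & wm_core
    if not mask.any():
        # degenerate draw (blob fell on a thin WM sliver); force the seed voxel
        mask = np.zeros(shape, bool)
        mask[tuple(coords[0])] = True
        profile[tuple(coords[0])] = 1.0
    signal = (contrast - 1.0) * WM_LEVEL * profile * wm_core
    return signal, mask


def generate_subject(template: TissueTemplate, protocol: ProtocolSpec,
                     lesion: bool, seed: int,
                     wm_texture_sd: float = WM_TEXTURE_SD) -> PhantomSample:
    """Synthesize one subject under one protocol.

    The noise-free anatomy (tissue mixture + optional lesions) depends only on
    (template, lesion, seed); the protocol then applies bias, affine transform,
    noise, and slice-thickness corruption. Two subjects generated with the
    same seed but different protocols therefore share an identical
    lesion_mask.
    """
    anat_rng = rng_from(seed, "anatomy")
    texture = (_wm_texture(template.shape, anat_rng, wm_texture_sd)
               if wm_texture_sd > 0 else np.zeros(template.shape))
    clean = (CSF_LEVEL * template.csf_prob
             + WM_LEVEL * (1.0 + texture) * template.wm_prob
             + GM_LEVEL * template.gm_prob)
    if lesion:
        signal, mask = _place_lesions(template, protocol.lesion_contrast, anat_rng)
        clean = clean + signal
        label = POSITIVE
    else:
        mask = np.zeros(template.shape, bool)
        label = NEGATIVE

    proto_rng = rng_from(seed, "protocol", protocol.protocol_id)
    img = clean * _bias_field(template.shape, protocol.bias_amplitude, proto_rng)
    img = protocol.gain * img + protocol.offset
    if protocol.noise_sd > 0:
        img = img + protocol.noise_sd * proto_rng.standard_normal(template.shape)
    if protocol.n_slices < template.shape[2]:
        img = _emulate_thick_slices(img, protocol.n_slices)
    return PhantomSample(image=Volume(img), label=label, lesion_mask=mask,
                         protocol_id=protocol.protocol_id,
                         truth_tissue=template, clean_image=clean)


def _emulate_thick_slices(img: np.ndarray, n_slices: int) -> np.ndarray:
    """Average the slice axis down to n_slices, then nearest-neighbor re-expand.

    Mimics how a thick-slice 2D acquisition looks after resampling to template
    space: full grid size, but only n_slices distinct slabs of information.
    """
    nz = img.shape[2]
    edges = np.linspace(0, nz, n_slices + 1)
    slabs = np.empty(img.shape[:2] + (n_slices,))
    for i in range(n_slices):
        lo, hi = int(np.floor(edges[i])), max(int(np.ceil(edges[i + 1])), int(np.floor(edges[i])) + 1)
        slabs[:, :, i] = img[:, :, lo:hi].mean(axis=2)
    idx = np.clip((np.arange(nz) / nz * n_slices).astype(int), 0, n_slices - 1)
    return slabs[:, :, idx]


def generate_cohort(template: TissueTemplate, protocols: Sequence[ProtocolSpec],
                    n_pos: int, n_neg: int, seed: int,
                    out_dir: str | Path | None = None,
                    ) -> tuple[list[PhantomSample], ScanManifest]:
    """Generate a cohort, assigning scans to protocols round-robin.

    Positives and negatives are interleaved so each protocol receives a
    near-balanced class mix. If ``out_dir`` is given, NIfTI volumes, the CSV
    manifest, and a JSON ground-truth sidecar are written there.
    """
    if not protocols:
        raise ValueError("need at least one protocol")
    if n_pos < 0 or n_neg < 0:
        raise ValueError("n_pos and n_neg must be >= 0")
    # distribute positives then negatives round-robin over protocols, so
    # per-protocol class counts are as even as the totals allow
    k = len(protocols)
    queues: list[list[bool]] = [[] for _ in range(k)]
    idx = 0
    for _ in range(n_pos):
        queues[idx % k].append(True)
        idx += 1
    for _ in range(n_neg):
        queues[idx % k].append(False)
        idx += 1
    plan: list[tuple[int, bool]] = []
    while any(queues):
        for p in range(k):
            if queues[p]:
                plan.append((p, queues[p].pop(0)))
    samples: list[PhantomSample] = []
    entries: list[ManifestEntry] = []
    out_dir = Path(out_dir) if out_dir is not None else None
    truth: dict[str, dict] = {}
    for i, (p, lesion) in enumerate(plan):
        proto = protocols[p]
        samp = generate_subject(template, proto, lesion, rng_from(seed, "subject", i).integers(2**31))
        scan_id = f"scan{i:04d}"
        path = str(out_dir / f"{scan_id}.nii.gz") if out_dir else f"{scan_id}.nii.gz"
        samples.append(samp)
        entries.append(ManifestEntry(scan_id, path, samp.label, proto.protocol_id,
                                     "phantom"))
        if out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)
            write_volume(samp.image, path)
            truth[scan_id] = {"label": samp.label,
                              "lesion_voxels": int(samp.lesion_mask.sum()),
                              "protocol_id": proto.protocol_id}
    manifest = ScanManifest(entries)
    if out_dir is not None:
        save_manifest(manifest, out_dir / "manifest.csv")
        (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return samples, manifest


def make_reference_cluster(cluster_maps: Sequence[np.ndarray | Volume],
                           n: int = 4) -> Volume:
    """Average the first ``n`` selected cluster membership maps into the fixed
    reference used for Dice-based cluster matching."""
    maps = [m.data if isinstance(m, Volume) else np.asarray(m, dtype=np.float64)
            for m in cluster_maps]
    if len(maps) < n:
        raise ValueError(f"need at least {n} cluster maps, got {len(maps)}")
    shapes = {m.shape for m in maps[:n]}
    if len(shapes) != 1:
        raise ValueError(f"cluster map shape mismatch: {sorted(shapes)}")
    ref = np.mean(maps[:n], axis=0)
    return Volume(np.clip(ref, 0.0, 1.0))


def default_protocols(n: int = 4) -> list[ProtocolSpec]:
    """The desk-scale protocol battery: varied gain/offset/bias/noise, with
    the last protocol a thick-slice (2D-like) acquisition."""
    base = [
        ProtocolSpec("siteA_3T", gain=1.0, offset=0.0, noise_sd=0.04, bias_amplitude=0.15),
        ProtocolSpec("siteB_1p5T", gain=1.8, offset=0.2, noise_sd=0.06, bias_amplitude=0.25),
        ProtocolSpec("siteC_3T", gain=0.7, offset=-0.05, noise_sd=0.03, bias_amplitude=0.10),
        ProtocolSpec("siteD_2D", gain=1.3, offset=0.1, noise_sd=0.05, bias_amplitude=0.20,
                     n_slices=12),
        ProtocolSpec("siteE_3T", gain=2.5, offset=0.5, noise_sd=0.05, bias_amplitude=0.30),
        ProtocolSpec("siteF_3T", gain=0.9, offset=0.0, noise_sd=0.08, bias_amplitude=0.15),
        ProtocolSpec("siteG_1p5T", gain=1.1, offset=-0.1, noise_sd=0.04, bias_amplitude=0.35),
        ProtocolSpec("siteH_3T", gain=1.6, offset=0.3, noise_sd=0.07, bias_amplitude=0.20),
        ProtocolSpec("siteI_3T", gain=0.8, offset=0.05, noise_sd=0.05, bias_amplitude=0.12),
        ProtocolSpec("siteJ_2D", gain=1.4, offset=0.0, noise_sd=0.06, bias_amplitude=0.18,
                     n_slices=14),
    ]
    if not 1 <= n <= len(base):
        raise ValueError(f"n must be in [1, {len(base)}]")
    return base[:n]


def easy_protocols(n: int = 4) -> list[ProtocolSpec]:
    """A benign protocol battery (low noise, mild bias, moderate lesion
    contrast) for end-to-end separability studies.

    Contrast is kept moderate (1.8) on purpose: pushing it much higher makes
    the brightest cluster lesion-only and spatially idiosyncratic, which
    degrades Dice matching against a fixed reference — the reference relies
    on the lesion-salient cluster retaining its bright-normal-WM component.
    """
    base = [
        ProtocolSpec("easyA_3T", gain=1.0, offset=0.0, noise_sd=0.02,
                     bias_amplitude=0.10, lesion_contrast=1.8),
        ProtocolSpec("easyB_1p5T", gain=1.5, offset=0.2, noise_sd=0.02,
                     bias_amplitude=0.10, lesion_contrast=1.8),
        ProtocolSpec("easyC_3T", gain=0.8, offset=-0.05, noise_sd=0.02,
                     bias_amplitude=0.08, lesion_contrast=1.8),
        ProtocolSpec("easyD_3T", gain=1.2, offset=0.1, noise_sd=0.02,
                     bias_amplitude=0.12, lesion_contrast=1.8),
        ProtocolSpec("easyE_3T", gain=2.0, offset=0.3, noise_sd=0.02,
                     bias_amplitude=0.10, lesion_contrast=1.8),
        ProtocolSpec("easyF_1p5T", gain=0.9, offset=0.05, noise_sd=0.03,
                     bias_amplitude=0.10, lesion_contrast=1.8),
    ]
    if not 1 <= n <= len(base):
        raise ValueError(f"n must be in [1, {len(base)}]")
    return base[:n]
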