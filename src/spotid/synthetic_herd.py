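"""Procedural generation of identity-bearing coat-pattern image datasets.

Emulates side-view photographs of a small dairy herd: each individual is
defined by a persistent set of dark body spots (Holstein-like, black on a
white body) drawn on a fixed side-view silhouette, and every photograph adds
nuisance variation — lighting, pose jitter, background clutter, occlusion,
sensor noise — that changes the pixels but never the identity.  A "simple
background" variant replaces the cluttered pen scene with a uniform
backdrop, mirroring background-removal experiments.

All randomness flows through explicit integer seeds, split into independent
streams (identity, pose, background, occlusion, photometric), so the same
arguments always reproduce the same bytes and changing the background mode
leaves every body pixel untouched.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path as FSPath

import numpy as np
from matplotlib.path import Path as MplPath
from PIL import Image

__all__ = [
    "Spot",
    "SpotIdentity",
    "RenderParams",
    "ManifestRecord",
    "DatasetManifest",
    "body_template_polygon",
    "make_identity",
    "spot_mask",
    "render_image",
    "generate_dataset",
    "load_manifest",
    "identity_separation",
]

MIN_IMAGE_SIDE = 64

# torso box, in body coordinates, inside which spot centers are sampled
_TORSO = (0.24, 0.80, 0.29, 0.60)  # u_min, u_max, v_min, v_max

_BODY_SHADE = 232.0
_SPOT_SHADE = 28.0


def body_template_polygon() -> np.ndarray:
    """(V, 2) array of the canonical side-view silhouette vertices (u, v)."""
    text = (
        resources.files("spotid").joinpath("resources/body_template.csv").read_text()
    )
    rows = [
        line.split(",")
        for line in text.splitlines()
        if line and not line.startswith("#") and not line.startswith("u,")
    ]
    return np.array([[float(u), float(v)] for u, v in rows])


@dataclass(frozen=True)
class Spot:
    """One wobbly-ellipse blob in body coordinates.

    The boundary radius is modulated as ``1 + lobe_amp*cos(lobes*theta +
    phase)``, giving each spot an irregular, coat-pattern-like outline.
    """

    u: float
    v: float
    ru: float
    rv: float
    rotation: float
    lobes: int
    lobe_amp: float
    phase: float


@dataclass(frozen=True)
class SpotIdentity:
    """A per-individual coat pattern: a seeded blob set on the body template."""

    id_label: int
    seed: int
    n_spots: int
    spots: tuple[Spot, ...]


@dataclass(frozen=True)
class RenderParams:
    """Nuisance-variation bounds for rendering.

    brightness_jitter is a multiplicative fraction (0.2 means the global
    illumination factor is drawn from [0.8, 1.2]); pose_jitter bounds the
    horizontal shear and the scale deviation; occlusion_fraction caps the
    image area covered by occluding rectangles; noise_sd is the additive
    Gaussian sensor noise in grey levels.
    """

    image_size: tuple[int, int] = (224, 224)
    background: str = "complex"
    brightness_jitter: float = 0.2
    pose_jitter: float = 0.08
    occlusion_fraction: float = 0.05
    noise_sd: float = 6.0

    def __post_init__(self) -> None:
        if self.background not in ("complex", "simple"):
            raise ValueError(f"background must be 'complex' or 'simple', got {self.background!r}")
        if not 0 <= self.brightness_jitter <= 0.4:
            raise ValueError("brightness_jitter must lie in [0, 0.4]")
        if not 0 <= self.occlusion_fraction <= 0.2:
            raise ValueError("occlusion_fraction must lie in [0, 0.2]")
        if self.noise_sd < 0 or self.pose_jitter < 0:
            raise ValueError("noise_sd and pose_jitter must be >= 0")


@dataclass(frozen=True)
class ManifestRecord:
    path: str  # relative to the manifest root
    id_label: int
    split: str = "none"  # train | val | none
    provenance: str = "original"  # original | augmented
    rotation: int = 0  # degrees applied at load time for augmented records


@dataclass
class DatasetManifest:
    records: list[ManifestRecord]
    n_identities: int
    root: str
    base_seed: int | None = None

    def paths(self) -> list[FSPath]:
        return [FSPath(self.root) / r.path for r in self.records]

    def labels(self) -> np.ndarray:
        return np.array([r.id_label for r in self.records], dtype=np.int64)


def make_identity(id_label: int, seed: int) -> SpotIdentity:
    """Deterministically derive an individual's spot pattern.

    The stream is keyed on ``(seed, id_label)``: the same pair always yields
    the same blob set, and every spot center lies inside the body silhouette.
    """
    if seed < 0:
        raise ValueError("seed must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, id_label]))
    poly = MplPath(body_template_polygon())
    n_spots = int(rng.integers(4, 21))
    u_min, u_max, v_min, v_max = _TORSO
    spots = []
    for _ in range(n_spots):
        while True:
            u = rng.uniform(u_min, u_max)
            v = rng.uniform(v_min, v_max)
            if poly.contains_point((u, v)):
                break
        spots.append(
            Spot(
                u=u,
                v=v,
                ru=rng.uniform(0.035, 0.095),
                rv=rng.uniform(0.030, 0.080),
                rotation=rng.uniform(0.0, np.pi),
                lobes=int(rng.integers(3, 8)),
                lobe_amp=rng.uniform(0.10, 0.35),
                phase=rng.uniform(0.0, 2 * np.pi),
            )
        )
    return SpotIdentity(id_label=id_label, seed=seed, n_spots=n_spots, spots=tuple(spots))


def _spot_membership(identity: SpotIdentity, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Boolean spot-coverage for arrays of body coordinates."""
    inside = np.zeros(u.shape, dtype=bool)
    for s in identity.spots:
        du, dv = u - s.u, v - s.v
        c, sn = np.cos(s.rotation), np.sin(s.rotation)
        x = (c * du + sn * dv) / s.ru
        y = (-sn * du + c * dv) / s.rv
        r = np.hypot(x, y)
        theta = np.arctan2(y, x)
        boundary = 1.0 + s.lobe_amp * np.cos(s.lobes * theta + s.phase)
        inside |= r <= boundary
    return inside


def _body_membership(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    poly = MplPath(body_template_polygon())
    pts = np.column_stack([u.ravel(), v.ravel()])
    return poly.contains_points(pts).reshape(u.shape)


def spot_mask(identity: SpotIdentity, resolution: int = 128) -> np.ndarray:
    """Canonical (pose-free) boolean spot mask on the body template."""
    g = (np.arange(resolution) + 0.5) / resolution
    u, v = np.meshgrid(g, g)
    return _spot_membership(identity, u, v) & _body_membership(u, v)


def _complex_background(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Cluttered pen scene: low-frequency color texture plus fence-like bars."""
    cells = 9
    coarse = rng.uniform(45, 190, size=(cells, cells, 3))
    img = np.asarray(
        Image.fromarray(coarse.astype(np.uint8)).resize((w, h), Image.BILINEAR),
        dtype=np.float64,
    )
    # fence: a few vertical posts and one horizontal rail
    n_posts = int(rng.integers(2, 5))
    for _ in range(n_posts):
        x0 = int(rng.integers(0, max(1, w - 8)))
        width = int(rng.integers(3, 9))
        shade = rng.uniform(30, 90)
        img[:, x0 : x0 + width] = shade
    y0 = int(rng.integers(h // 6, h // 2))
    height = int(rng.integers(3, 8))
    img[y0 : y0 + height, :] = rng.uniform(35, 95)
    return img


def render_image(
    identity: SpotIdentity, params: RenderParams, seed: int
) -> np.ndarray:
    """Render one (H, W, 3) uint8 photograph of an individual.

    The identity's spots are composited over the chosen background with
    seeded pose, occlusion and photometric nuisance, each drawn from an
    independent stream so the background mode never perturbs body pixels.
    """
    h, w = params.image_size
    if h < MIN_IMAGE_SIDE or w < MIN_IMAGE_SIDE:
        raise ValueError(
            f"image_size must be at least {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}, got {params.image_size}"
        )
    ss = np.random.SeedSequence([int(seed)])
    pose_rng, bg_rng, occ_rng, photo_rng = map(np.random.default_rng, ss.spawn(4))

    # pose: scale, horizontal shear, small translation
    pj = params.pose_jitter
    scale = 1.0 + pose_rng.uniform(-pj, pj)
    shear = pose_rng.uniform(-pj, pj)
    tx = pose_rng.uniform(-pj / 2, pj / 2)
    ty = pose_rng.uniform(-pj / 2, pj / 2)

    if params.background == "simple":
        img = np.full((h, w, 3), 128.0)
    else:
        img = _complex_background(h, w, bg_rng)

    # map every pixel to body coordinates via the inverse pose transform
    py, px = np.meshgrid((np.arange(h) + 0.5) / h, (np.arange(w) + 0.5) / w, indexing="ij")
    sy = 0.88 * scale
    sx = 0.92 * scale
    v = (py - (0.52 + ty)) / sy + 0.53
    u = ((px - (0.50 + tx)) - shear * (v - 0.5)) / sx + 0.50
    body = _body_membership(u, v)
    spots = _spot_membership(identity, u, v) & body
    shading = 1.0 - 0.12 * np.clip(v, 0, 1)  # mild top-lit vertical shading
    img[body] = (_BODY_SHADE * shading[body])[:, None]
    img[spots] = (_SPOT_SHADE + 40.0 * (1 - shading[spots]))[:, None]

    # occluding rectangles (fence posts, other animals) up to the area cap
    area_left = params.occlusion_fraction * h * w
    while area_left > 0.005 * h * w:
        rh = int(occ_rng.integers(h // 10, h // 3))
        rw = int(occ_rng.integers(w // 12, w // 4))
        if rh * rw > area_left:
            break
        y0 = int(occ_rng.integers(0, h - rh))
        x0 = int(occ_rng.integers(0, w - rw))
        img[y0 : y0 + rh, x0 : x0 + rw] = occ_rng.uniform(40, 170, size=3)
        area_left -= rh * rw
    # consume the stream identically whether or not occlusion is enabled
    # (occlusion_fraction=0 simply draws nothing)

    factor = 1.0 + photo_rng.uniform(-params.brightness_jitter, params.brightness_jitter)
    img = img * factor
    if params.noise_sd > 0:
        img = img + photo_rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def _render_seed(base_seed: int, id_label: int, index: int) -> int:
    return int(
        np.random.SeedSequence([base_seed, id_label, index]).generate_state(1)[0]
        % (2**31)
    )


def generate_dataset(
    n_identities: int,
    per_identity: int,
    params: RenderParams,
    seed: int,
    out_dir: str | FSPath,
) -> DatasetManifest:
    """Write a one-folder-per-identity PNG dataset plus a CSV manifest.

    A fixed ``(n_identities, per_identity, params, seed)`` tuple reproduces
    the dataset byte-for-byte.  Identification needs at least two
    individuals.
    """
    if n_identities < 2:
        raise ValueError("need at least 2 identities for identification")
    if per_identity < 1:
        raise ValueError("per_identity must be >= 1")
    root = FSPath(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    records: list[ManifestRecord] = []
    for i in range(n_identities):
        ident = make_identity(i, seed)
        folder = root / f"id_{i:02d}"
        folder.mkdir(exist_ok=True)
        for j in range(per_identity):
            img = render_image(ident, params, _render_seed(seed, i, j))
            rel = f"id_{i:02d}/img_{j:03d}.png"
            Image.fromarray(img).save(root / rel)
            records.append(ManifestRecord(path=rel, id_label=i))
    manifest = DatasetManifest(
        records=records, n_identities=n_identities, root=str(root), base_seed=seed
    )
    save_manifest(manifest, root / "manifest.csv")
    meta = {
        "n_identities": n_identities,
        "per_identity": per_identity,
        "seed": seed,
        "params": {
            "image_size": list(params.image_size),
            "background": params.background,
            "brightness_jitter": params.brightness_jitter,
            "pose_jitter": params.pose_jitter,
            "occlusion_fraction": params.occlusion_fraction,
            "noise_sd": params.noise_sd,
        },
    }
    (root / "herd.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return manifest


def save_manifest(manifest: DatasetManifest, path: str | FSPath) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "id_label", "split", "provenance", "rotation"])
        for r in manifest.records:
            writer.writerow([r.path, r.id_label, r.split, r.provenance, r.rotation])


def load_manifest(root: str | FSPath, csv_path: str | FSPath | None = None) -> DatasetManifest:
    """Read a manifest CSV (and herd.json metadata when present)."""
    root = FSPath(root)
    csv_path = FSPath(csv_path) if csv_path else root / "manifest.csv"
    records = []
    with open(csv_path) as fh:
        for row in csv.DictReader(fh):
            records.append(
                ManifestRecord(
                    path=row["path"],
                    id_label=int(row["id_label"]),
                    split=row.get("split", "none"),
                    provenance=row.get("provenance", "original"),
                    rotation=int(row.get("rotation", 0)),
                )
            )
    n_identities = len({r.id_label for r in records})
    base_seed = None
    meta_path = root / "herd.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        n_identities = meta.get("n_identities", n_identities)
        base_seed = meta.get("seed")
    return DatasetManifest(
        records=records, n_identities=n_identities, root=str(root), base_seed=base_seed
    )


def identity_separation(manifest: DatasetManifest, resolution: int = 128) -> np.ndarray:
    """Pairwise Jaccard overlap of canonical spot masks; diagonal is 1.

    Values near 1 off the diagonal flag degenerate (near-duplicate)
    identities; the default herd stays well below 0.5.  Raises
    FileNotFoundError if manifest image files are missing on disk.
    """
    if manifest.n_identities < 2:
        raise ValueError("need at least 2 identities")
    if manifest.base_seed is None:
        raise ValueError("manifest lacks the base seed needed to rebuild identities")
    for p in manifest.paths():
        if not p.exists():
            raise FileNotFoundError(str(p))
    masks = [
        spot_mask(make_identity(i, manifest.base_seed), resolution)
        for i in range(manifest.n_identities)
    ]
    n = len(masks)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            inter = np.logical_and(masks[i], masks[j]).sum()
            union = np.logical_or(masks[i], masks[j]).sum()
            jac = inter / union if union else 1.0
            out[i, j] = out[j, i] = jac
    if np.any(out[np.triu_indices(n, k=1)] > 0.95):
        warnings.warn("near-duplicate identities detected (spot-mask overlap > 0.95)")
    return out
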