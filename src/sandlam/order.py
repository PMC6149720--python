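"""Trajectory observables for coarse-grained bilayer frames: P2 bond order
parameters, number-density profiles, phosphate-to-phosphate thickness,
lateral 2D RDF and inter-group distances.

Conventions: the membrane normal is an axis of the orthorhombic periodic
box (default z); the bilayer center is the per-frame mean coordinate of all
lipid beads (robust to membrane drift); leaflets are assigned by the sign
of the centered normal coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .models import ParticleFrame

#: bead names treated as water when centering (excluded from the lipid set)
WATER_LABELS = {"W", "WF", "SOL"}


def _check_frames(frames) -> list[ParticleFrame]:
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    return frames


def _lipid_center(frame: ParticleFrame, axis: int) -> float:
    mask = ~np.isin(frame.labels, sorted(WATER_LABELS))
    if not mask.any():
        mask = np.ones(len(frame.labels), bool)
    return float(frame.positions[mask, axis].mean())


def _minimum_image(vec: np.ndarray, box: np.ndarray) -> np.ndarray:
    return vec - box * np.round(vec / box)


@dataclass
class OrderParameterResult:
    p2: float
    stderr: float
    n_bonds: int


def order_parameter(frames, bonds: list[tuple[str, str]],
                    normal_axis: int = 2) -> dict[tuple[str, str], OrderParameterResult]:
    """P2 = ½(3⟨cos²θ⟩ − 1) per bond type, pooled over frames and molecules.

    θ is the angle between the bond vector (second bead minus first, paired
    within each residue) and the membrane normal. Values lie in [−0.5, 1]:
    1 for bonds along the normal, −0.5 perpendicular, 0 isotropic. The
    standard error is that of the pooled per-bond P2 samples.
    """
    frames = _check_frames(frames)
    out = {}
    for la, lb in bonds:
        samples = []
        for frame in frames:
            ia = np.flatnonzero(frame.labels == la)
            ib = np.flatnonzero(frame.labels == lb)
            if ia.size == 0 or ib.size == 0:
                raise ValueError(f"bond ({la}, {lb}): label not found in frame")
            res_a = {r: i for i, r in zip(ia, frame.resids[ia])}
            res_b = {r: i for i, r in zip(ib, frame.resids[ib])}
            shared = sorted(set(res_a) & set(res_b))
            if not shared:
                raise ValueError(f"bond ({la}, {lb}): no residue contains both beads")
            va = frame.positions[[res_a[r] for r in shared]]
            vb = frame.positions[[res_b[r] for r in shared]]
            vec = _minimum_image(vb - va, frame.box)
            norm = np.linalg.norm(vec, axis=1)
            cos2 = (vec[:, normal_axis] / norm) ** 2
            samples.append(0.5 * (3.0 * cos2 - 1.0))
        pooled = np.concatenate(samples)
        se = float(pooled.std(ddof=1) / math.sqrt(pooled.size)) if pooled.size > 1 else 0.0
        out[(la, lb)] = OrderParameterResult(float(pooled.mean()), se, pooled.size)
    return out


@dataclass
class DensityProfileResult:
    z: np.ndarray          # |z| bin centers, Å
    counts: np.ndarray     # raw bead counts per bin (sums to selection size × frames)
    density: np.ndarray    # beads per Å³ (leaflet-folded)
    span90: tuple[float, float]


def density_profile(frames, labels, normal_axis: int = 2,
                    bin_width: float = 1.0) -> DensityProfileResult:
    """Leaflet-folded number density of a bead selection vs |z|.

    z is measured from the per-frame bilayer center and folded to |z| (both
    leaflets pooled); density normalizes by box cross-section × bin width ×
    n_frames, counting both leaflets into the same |z| bin. ``span90`` is
    the [5th, 95th] percentile interval of the |z| samples — the central-90%
    localization of the group.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    frames = _check_frames(frames)
    absz, area = [], []
    for frame in frames:
        mask = frame.select(labels)
        if not mask.any():
            raise ValueError(f"empty selection for labels {labels}")
        c = _lipid_center(frame, normal_axis)
        absz.append(np.abs(frame.positions[mask, normal_axis] - c))
        lateral = [i for i in range(3) if i != normal_axis]
        area.append(frame.box[lateral[0]] * frame.box[lateral[1]])
    absz = np.concatenate(absz)
    n_bins = max(1, int(math.ceil(absz.max() / bin_width))) if absz.max() > 0 else 1
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)[: n_bins + 1]
    counts, _ = np.histogram(absz, bins=edges)
    density = counts / (float(np.mean(area)) * bin_width * len(frames))
    lo, hi = np.percentile(absz, [5.0, 95.0])
    return DensityProfileResult(z=0.5 * (edges[:-1] + edges[1:]), counts=counts,
                                density=density, span90=(float(lo), float(hi)))


def bilayer_thickness_pp(frames, phosphate_label: str = "PO4",
                         normal_axis: int = 2) -> float:
    """D_PP: distance between mean phosphate positions of the two leaflets.

    Leaflets are split by the sign of the centered normal coordinate;
    an unpopulated leaflet raises. Averaged over frames.
    """
    frames = _check_frames(frames)
    values = []
    for frame in frames:
        mask = frame.labels == phosphate_label
        if not mask.any():
            raise ValueError(f"no beads labelled {phosphate_label}")
        z = frame.positions[mask, normal_axis] - _lipid_center(frame, normal_axis)
        upper, lower = z[z > 0], z[z < 0]
        if upper.size == 0 or lower.size == 0:
            raise ValueError("one leaflet has no phosphate beads")
        values.append(float(upper.mean() - lower.mean()))
    return float(np.mean(values))


@dataclass
class RDFResult:
    r: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    expected: np.ndarray
    n_particles: int


def lateral_rdf(frames, label: str, leaflet: str | None = None,
                bin_width: float = 0.5, r_max: float | None = None,
                normal_axis: int = 2) -> RDFResult:
    """Lateral (2D, in-plane) radial distribution function of one bead type.

    Pair distances use the minimum-image convention in the two lateral box
    directions only. Normalization is the 2D ideal gas: expected pairs per
    annulus = N(N−1)/2 · 2πr·dr/A, so g → 1 at large r for homogeneous
    systems. ``leaflet`` ('upper'/'lower') restricts the selection by the
    sign of the centered normal coordinate.
    """
    frames = _check_frames(frames)
    lateral = [i for i in range(3) if i != normal_axis]
    box0 = frames[0].box
    limit = min(box0[lateral[0]], box0[lateral[1]]) / 2.0
    if r_max is None:
        r_max = limit
    if r_max > limit + 1e-9:
        raise ValueError(f"r_max = {r_max} exceeds half the smallest lateral "
                         f"box length ({limit})")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    expected = np.zeros_like(counts)
    n_sel = 0
    for frame in frames:
        mask = frame.labels == label
        if leaflet is not None:
            z = frame.positions[:, normal_axis] - _lipid_center(frame, normal_axis)
            mask &= (z > 0) if leaflet == "upper" else (z < 0)
        pts = frame.positions[mask][:, lateral]
        n = len(pts)
        if n < 2:
            raise ValueError("need at least two selected particles for an RDF")
        n_sel = n
        boxl = frame.box[lateral]
        d = pts[:, None, :] - pts[None, :, :]
        d = _minimum_image(d, boxl)
        r = np.sqrt((d**2).sum(axis=-1))
        iu = np.triu_indices(n, k=1)
        c, _ = np.histogram(r[iu], bins=edges)
        counts += c
        area = boxl[0] * boxl[1]
        ann = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        expected += n * (n - 1) / 2.0 * ann / area
    g = np.divide(counts, expected, out=np.zeros_like(counts), where=expected > 0)
    return RDFResult(r=0.5 * (edges[:-1] + edges[1:]), g=g, counts=counts,
                     expected=expected, n_particles=n_sel)


def group_distance(frames, label_a, label_b, normal_axis: int = 2) -> float:
    """Signed normal distance between two groups' mean positions.

    Computed per leaflet from |z| of each group's beads relative to the
    bilayer center, then averaged over leaflets and frames. Positive means
    group A sits farther from the bilayer center than group B.
    """
    frames = _check_frames(frames)
    values = []
    for frame in frames:
        c = _lipid_center(frame, normal_axis)
        z = frame.positions[:, normal_axis] - c
        ma, mb = frame.select(label_a), frame.select(label_b)
        if not ma.any() or not mb.any():
            raise ValueError("empty group selection")
        per_leaflet = []
        for side in (z > 0, z < 0):
            za, zb = np.abs(z[ma & side]), np.abs(z[mb & side])
            if za.size and zb.size:
                per_leaflet.append(float(za.mean() - zb.mean()))
        if not per_leaflet:
            raise ValueError("groups do not share a populated leaflet")
        values.append(float(np.mean(per_leaflet)))
    return float(np.mean(values))
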