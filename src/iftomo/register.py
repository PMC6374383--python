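"""Rigid slice-to-slice registration of serial sections.

Sections are physical slices of one embedded block, so a rigid model
(in-plane translation + rotation) suffices; no deformable correction is
attempted. Registration runs on the nuclear (DAPI) channel: nuclei are
sparse blobs present in every section and every staining round, so
normalized cross-correlation on lightly smoothed images is a robust
similarity metric with a brute-force oracle.

``register_pair`` does a coarse rotation sweep (0.5 degree steps), solving
the translation for each candidate angle by phase correlation, then
refines the angle by bounded scalar minimization. ``align_stack`` chains
consecutive-pair transforms to a reference section and resamples every
channel once with the absolute transform. ``fuse_reprobe`` aligns a
re-stained (eluted and re-probed) round of the same physical section via
its DAPI channel and merges the new antibody channels, which is how more
than four fluorescent channels per section are obtained.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.registration import phase_cross_correlation

from .section import SectionImage
from .transforms import RigidTransform2D, compose, identity, warp_image
from .phantom import quantize

log = logging.getLogger(__name__)

DEFAULT_CONFIDENCE_FLOOR = 0.1
DEFAULT_ANGLE_STEP = 0.5  # degrees


class RegistrationError(RuntimeError):
    """Raised when a registration that must not silently fail falls below
    the confidence floor (e.g. re-probe fusion)."""


@dataclass
class AlignmentResult:
    """Pairwise and chained (absolute) transforms for an aligned stack.

    ``pairwise[i]`` maps section i into section i-1's frame (``pairwise[0]``
    is the identity placeholder); ``absolute[i]`` maps section i into the
    reference section's frame and satisfies
    ``absolute[i] = compose(absolute[i-1], pairwise[i])`` for i past the
    reference. ``flagged`` lists sections whose pair registration fell
    below the confidence floor and were assigned the identity (recorded,
    never dropped).
    """

    pairwise: list[RigidTransform2D]
    absolute: list[RigidTransform2D]
    scores: list[float]
    reference_index: int = 0
    flagged: list[int] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "reference_index": self.reference_index,
            "pairwise": [t.as_dict() for t in self.pairwise],
            "absolute": [t.as_dict() for t in self.absolute],
            "scores": self.scores,
            "flagged": self.flagged,
        }


def _ncc_valid(
    fixed: np.ndarray,
    warped: np.ndarray,
    valid: np.ndarray,
    min_valid_frac: float = 0.5,
) -> float:
    # a candidate that throws more than half the frame out of bounds cannot
    # be assessed reliably (tiny overlaps produce spurious correlations)
    if valid.mean() < min_valid_frac:
        return 0.0
    a = fixed[valid]
    b = warped[valid]
    if a.size < 16:
        return 0.0
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def _solve_translation(fixed, moving, theta, upsample):
    """Best translation for a fixed candidate angle, via phase correlation."""
    rotated = warp_image(moving, RigidTransform2D(0, 0, theta))
    shift, _, _ = phase_cross_correlation(
        fixed, rotated, upsample_factor=upsample, normalization=None
    )
    t = RigidTransform2D(float(shift[1]), float(shift[0]), theta)
    warped = warp_image(moving, t)
    valid = warp_image(np.ones_like(moving), t) > 0.999
    return t, _ncc_valid(fixed, warped, valid)


def _detect_peaks(img: np.ndarray, min_distance: int = 4) -> np.ndarray:
    """Sub-pixel nucleus center landmarks (x, y) in a smoothed DAPI image.

    A nucleus projects to the same in-plane center in every section it
    intersects, so center positions are stable landmarks across
    consecutive sections even though apparent radii change. Centers are
    found as local maxima of the euclidean distance transform of the
    foreground mask (the incircle center of a disk is its center,
    independent of the disk's radius), refined to sub-pixel as the
    weighted centroid of the near-peak plateau.
    """
    mx = img.max()
    if mx <= 0:
        return np.empty((0, 2))
    mask = img > max(0.2 * mx, 3.0 * max(np.median(img), 1e-6))
    dt = ndimage.distance_transform_edt(mask)
    coords = peak_local_max(dt, min_distance=min_distance, threshold_abs=2.0)
    pts = []
    for y, x in coords:
        y0, y1 = max(y - 4, 0), y + 5
        x0, x1 = max(x - 4, 0), x + 5
        win = dt[y0:y1, x0:x1]
        top = win >= 0.8 * dt[y, x]
        ys, xs = np.nonzero(top)
        w = win[top]
        pts.append(
            (float((xs * w).sum() / w.sum() + x0), float((ys * w).sum() / w.sum() + y0))
        )
    return np.asarray(pts) if pts else np.empty((0, 2))


def _procrustes_rigid(src: np.ndarray, dst: np.ndarray, center) -> RigidTransform2D:
    """Least-squares rigid transform (about ``center``) mapping src -> dst."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    a = src - mu_s
    b = dst - mu_d
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, d]) @ u.T
    theta = math.degrees(math.atan2(rot[1, 0], rot[0, 0]))
    t0 = mu_d - rot @ mu_s  # p' = rot @ p + t0
    c = np.asarray(center)
    t = t0 - c + rot @ c
    return RigidTransform2D(float(t[0]), float(t[1]), theta)


def _landmark_refine(
    f: np.ndarray,
    m: np.ndarray,
    start: RigidTransform2D,
    match_radius: float = 4.0,
    iterations: int = 3,
) -> RigidTransform2D | None:
    """Refine a coarse lock by matching nucleus peaks (ICP-style).

    Mutual nearest-neighbor correspondences within ``match_radius`` px of
    the current transform feed a closed-form rigid Procrustes fit; three
    iterations suffice since peak positions are section-invariant. Returns
    None when fewer than 3 landmarks match (refinement not possible).
    """
    pf = _detect_peaks(f)
    pm = _detect_peaks(m)
    if len(pf) < 4 or len(pm) < 4:
        return None
    h, w = f.shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    t = start
    radii = np.linspace(match_radius, match_radius / 2.0, iterations)
    final_resid = np.inf
    for radius in radii:
        moved = t.apply_to_points(pm, center=center)
        tree = cKDTree(pf)
        dist, idx = tree.query(moved, distance_upper_bound=radius)
        ok = np.isfinite(dist)
        if ok.sum() < 4:
            return None
        # enforce one-to-one: keep the closest match per fixed peak
        pairs: dict[int, int] = {}
        for k in np.flatnonzero(ok):
            j = idx[k]
            if j not in pairs or dist[k] < dist[pairs[j]]:
                pairs[j] = k
        src = pm[list(pairs.values())]
        dst = pf[list(pairs.keys())]
        if len(src) < 4:
            return None
        t = _procrustes_rigid(src, dst, center)
        moved = t.apply_to_points(src, center=center)
        final_resid = float(np.sqrt(((moved - dst) ** 2).sum(axis=1)).mean())
    if final_resid > 1.0:  # correspondences inconsistent with a rigid fit
        return None
    return t


def _landmark_global(
    f: np.ndarray,
    m: np.ndarray,
    max_rotation: float,
    angle_step: float = 1.0,
    inlier_radius: float = 2.0,
) -> list[RigidTransform2D]:
    """Globally search rigid transforms aligning the two landmark patterns.

    For every candidate correspondence (one landmark from each image) and
    every candidate rotation within the bound, the implied translation is
    scored by how many landmarks find a partner within ``inlier_radius``;
    the best hypotheses are polished by a rigid Procrustes fit on their
    inliers. Returns candidate transforms ordered by inlier support (empty
    when either image yields fewer than 4 landmarks).
    """
    pf = _detect_peaks(f)
    pm = _detect_peaks(m)
    if len(pf) < 4 or len(pm) < 4:
        return []
    h, w = f.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tree = cKDTree(pf)
    thetas = np.arange(-max_rotation, max_rotation + angle_step / 2, angle_step)
    hypotheses: list[tuple[int, float, RigidTransform2D]] = []
    for th in thetas:
        a = math.radians(th)
        rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        rotated = (pm - center) @ rot.T + center
        for j in range(len(pm)):
            for i in range(len(pf)):
                tvec = pf[i] - rotated[j]
                moved = rotated + tvec
                dist, idx = tree.query(moved, distance_upper_bound=inlier_radius)
                ok = np.isfinite(dist)
                n_in = int(ok.sum())
                if n_in < 4:
                    continue
                # one-to-one inlier set
                pairs: dict[int, int] = {}
                for k in np.flatnonzero(ok):
                    q = idx[k]
                    if q not in pairs or dist[k] < dist[pairs[q]]:
                        pairs[q] = k
                if len(pairs) < 4:
                    continue
                t = _procrustes_rigid(
                    pm[list(pairs.values())], pf[list(pairs.keys())], center
                )
                resid = t.apply_to_points(pm[list(pairs.values())], center=center)
                rms = float(
                    np.sqrt(((resid - pf[list(pairs.keys())]) ** 2).sum(axis=1)).mean()
                )
                if rms <= 1.0 and abs(t.theta) <= max_rotation + angle_step:
                    hypotheses.append((len(pairs), rms, t))
    if not hypotheses:
        return []
    hypotheses.sort(key=lambda x: (-x[0], x[1]))
    # deduplicate near-identical transforms, keep a handful of the best
    out: list[RigidTransform2D] = []
    for _, _, t in hypotheses:
        if all(
            abs(t.tx - o.tx) > 1.0 or abs(t.ty - o.ty) > 1.0 or abs(t.theta - o.theta) > 0.5
            for o in out
        ):
            out.append(t)
        if len(out) >= 3:
            break
    return out


def register_pair(
    fixed: np.ndarray,
    moving: np.ndarray,
    max_rotation: float = 10.0,
    max_translation: float | None = None,
    angle_step: float = DEFAULT_ANGLE_STEP,
    confidence_floor: float = DEFAULT_CONFIDENCE_FLOOR,
    smooth_sigma: float = 1.0,
    upsample: int = 20,
) -> tuple[RigidTransform2D, float]:
    """Rigid transform mapping ``moving`` onto ``fixed``, with its score.

    Coarse search over rotation candidates in
    [-max_rotation, +max_rotation] at ``angle_step`` degree steps, each
    candidate's translation solved by phase correlation; the best angle is
    then refined by bounded scalar minimization of the negative normalized
    correlation. Returns ``(transform, score)``; a score below
    ``confidence_floor`` yields the identity with score 0 and a warning so
    the section can be flagged for manual review.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError(f"shape mismatch: {fixed.shape} vs {moving.shape}")
    if fixed.std() == 0 or moving.std() == 0:
        raise ValueError("zero-variance input image")
    f = gaussian(fixed, sigma=smooth_sigma, preserve_range=True)
    m = gaussian(moving, sigma=smooth_sigma, preserve_range=True)

    def ncc_at(t: RigidTransform2D) -> float:
        warped = warp_image(m, t)
        valid = warp_image(np.ones_like(m), t) > 0.999
        return _ncc_valid(f, warped, valid)

    # stage 1: global landmark (nucleus-center) correspondence search —
    # exact and rotation-sharp whenever both images yield enough landmarks
    lm_best, lm_best_score = None, -np.inf
    for cand in _landmark_global(f, m, max_rotation):
        s = ncc_at(cand)
        if s > lm_best_score:
            lm_best, lm_best_score = cand, s

    # stage 2: coarse correlation sweep over rotation candidates — the
    # fallback that needs no detectable landmarks
    thetas = np.arange(-max_rotation, max_rotation + angle_step / 2, angle_step)
    if 0.0 not in thetas:
        thetas = np.sort(np.append(thetas, 0.0))
    best_t, best_score = identity(), -np.inf
    for th in thetas:
        t, score = _solve_translation(f, m, float(th), upsample=1)
        if score > best_score:
            best_t, best_score = t, score

    # local angle refinement around the best coarse candidate
    lo = best_t.theta - angle_step
    hi = best_t.theta + angle_step
    cache: dict[float, tuple[RigidTransform2D, float]] = {}

    def neg_score(th: float) -> float:
        key = round(th, 6)
        if key not in cache:
            cache[key] = _solve_translation(f, m, th, upsample=upsample)
        return -cache[key][1]

    if max_rotation > 0:
        res = minimize_scalar(
            neg_score, bounds=(lo, hi), method="bounded",
            options={"xatol": 0.01},
        )
        best_t, best_score = cache[round(float(res.x), 6)]
    else:
        best_t, best_score = _solve_translation(f, m, 0.0, upsample=upsample)

    # landmark polish of the correlation lock: nucleus centers are
    # section-invariant, so a point-pattern rigid fit resolves the
    # rotation/translation trade-off a correlation ridge on blobs leaves flat
    lm = _landmark_refine(f, m, best_t)
    if lm is not None:
        lm_score = ncc_at(lm)
        if lm_score >= best_score - 0.05:
            best_t, best_score = lm, max(lm_score, 0.0)

    # a landmark-supported global solution wins unless the correlation
    # evidence against it is decisive
    if lm_best is not None and lm_best_score >= best_score - 0.05:
        best_t, best_score = lm_best, max(lm_best_score, 0.0)

    if max_translation is not None and (
        abs(best_t.tx) > max_translation or abs(best_t.ty) > max_translation
    ):
        warnings.warn(
            f"recovered translation ({best_t.tx:.1f}, {best_t.ty:.1f}) exceeds "
            f"max_translation={max_translation}; returning identity",
            stacklevel=2,
        )
        return identity(), 0.0
    if best_score < confidence_floor:
        warnings.warn(
            f"registration score {best_score:.3f} below confidence floor "
            f"{confidence_floor}; returning identity (flag for manual review)",
            stacklevel=2,
        )
        return identity(), 0.0
    return best_t, float(best_score)


def align_stack(
    sections: list[SectionImage],
    channel: str = "DAPI",
    reference_index: int = 0,
    **register_kwargs,
) -> tuple[AlignmentResult, list[SectionImage]]:
    """Align an ordered serial-section stack on the named channel.

    Registers each consecutive pair (section i as moving, i-1 as fixed),
    chains the pairwise transforms into absolute transforms relative to
    the reference section, and resamples all channels of every section
    once with its absolute transform (bilinear, zero fill). Pairs whose
    score falls below the confidence floor get the identity and are
    recorded in ``flagged``.
    """
    n = len(sections)
    if n < 2:
        raise ValueError("align_stack needs at least 2 sections")
    shapes = {s.shape for s in sections}
    if len(shapes) != 1:
        raise ValueError(f"sections have mixed shapes: {shapes}")
    if not 0 <= reference_index < n:
        raise ValueError(f"reference_index {reference_index} out of range")

    pairwise = [identity()]
    scores = [1.0]
    flagged = []
    for i in range(1, n):
        t, score = register_pair(
            sections[i - 1].channel(channel),
            sections[i].channel(channel),
            **register_kwargs,
        )
        pairwise.append(t)
        scores.append(score)
        if score == 0.0:
            flagged.append(i)
        log.info("pair %d -> %d: %s score=%.3f", i, i - 1, t, score)

    absolute: list[RigidTransform2D | None] = [None] * n
    absolute[reference_index] = identity()
    for i in range(reference_index + 1, n):
        absolute[i] = compose(absolute[i - 1], pairwise[i])
    for i in range(reference_index - 1, -1, -1):
        absolute[i] = compose(absolute[i + 1], pairwise[i + 1].inverse())

    aligned = []
    for sec, t in zip(sections, absolute):
        if t.is_identity():
            aligned.append(sec.with_data(sec.data.copy()))
        else:
            warped = warp_image(sec.data, t)
            bit_depth = 8 * sec.data.dtype.itemsize
            aligned.append(sec.with_data(quantize(warped, bit_depth).astype(sec.data.dtype)))
    result = AlignmentResult(
        pairwise=pairwise,
        absolute=list(absolute),
        scores=scores,
        reference_index=reference_index,
        flagged=flagged,
    )
    return result, aligned


def fuse_reprobe(
    round1: SectionImage,
    round2: SectionImage,
    dapi_channel: str = "DAPI",
    **register_kwargs,
) -> tuple[SectionImage, RigidTransform2D]:
    """Merge a re-probed imaging round of the same physical section.

    round2 is registered to round1 on the shared DAPI channel; the fused
    section carries round1's channels plus round2's non-DAPI channels,
    resampled into round1's frame. Duplicate channel names get a ``_r2``
    suffix. A registration below the confidence floor raises
    :class:`RegistrationError` — re-probe fusion must not silently
    misalign.
    """
    fixed = round1.channel(dapi_channel)
    moving = round2.channel(dapi_channel)
    t, score = register_pair(fixed, moving, **register_kwargs)
    floor = register_kwargs.get("confidence_floor", DEFAULT_CONFIDENCE_FLOOR)
    if score < floor or score == 0.0:
        raise RegistrationError(
            f"re-probe DAPI registration failed (score {score:.3f} < floor {floor})"
        )
    names = list(round1.channel_names)
    planes = [round1.data[i] for i in range(round1.n_channels)]
    bit_depth = 8 * round1.data.dtype.itemsize
    for i, name in enumerate(round2.channel_names):
        if name == dapi_channel:
            continue
        plane = round2.data[i]
        if not t.is_identity():
            plane = quantize(warp_image(plane, t), bit_depth).astype(round1.data.dtype)
        out_name = name if name not in names else f"{name}_r2"
        names.append(out_name)
        planes.append(plane)
    fused = SectionImage(
        data=np.stack(planes),
        channel_names=names,
        index=round1.index,
        pixel_size=round1.pixel_size,
        thickness=round1.thickness,
    )
    return fused, t
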