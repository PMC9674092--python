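"""Cilium morphometry from segmented 3D traces.

Each cilium is an ordered 3D polyline (um). Measures: arc length, end-to-end
chord, tortuosity (arc/chord, >= 1), and a length proxy — the longest edge
of an oriented bounding box of the point set, mirroring length estimation on
segmented surfaces. Morphology classes (straight / bent / contorted) are
assigned from explicit tortuosity and self-proximity rules, and genotype
groups are compared distributionally (two-sample Kolmogorov-Smirnov on
lengths, one-way ANOVA at both cilium and mouse level, class proportions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import f_oneway, ks_2samp

log = logging.getLogger(__name__)

__all__ = [
    "CiliumMeasures",
    "GroupComparison",
    "read_cilia_csv",
    "measure_cilium",
    "measure_table",
    "classify_morphology",
    "compare_groups",
]

MORPHOLOGY_CLASSES = ("straight", "bent", "contorted")


@dataclass(frozen=True)
class CiliumMeasures:
    arc_length: float     # um, sum of segment norms
    end_to_end: float     # um, chord between endpoints
    length_proxy: float   # um, longest OBB edge
    tortuosity: float     # arc / chord, dimensionless >= 1


@dataclass
class GroupComparison:
    groups: tuple
    ks_statistic: float
    ks_pvalue: float
    anova_f: float            # cilium as unit of analysis
    anova_pvalue: float
    anova_f_mouse: float      # per-mouse means as unit of analysis
    anova_pvalue_mouse: float
    per_mouse_means: pd.DataFrame
    class_proportions: pd.DataFrame


def read_cilia_csv(path):
    """Read a trace table (schema of the synthetic writer, unit um).

    The unit declaration (``# unit=um`` header or a ``unit`` column with
    value ``um``) is required; mixed or missing units are rejected.
    """
    with open(path) as fh:
        head = [next(fh, "") for _ in range(5)]
    declared = any("unit=um" in line for line in head if line.startswith("#"))
    df = pd.read_csv(path, comment="#")
    if "unit" in df.columns:
        units = set(df["unit"].unique())
        if units != {"um"}:
            raise ValueError(f"expected unit 'um' for every row, got {units}")
        df = df.drop(columns="unit")
    elif not declared:
        raise ValueError("no unit declaration (header '# unit=um' or a "
                         "'unit' column) in trace file")
    required = {"cilium_id", "mouse_id", "genotype", "point_index",
                "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# oriented bounding box
# ---------------------------------------------------------------------------

def _rect_key(extents):
    """Lexicographic objective: minimal volume, then shortest longest edge."""
    ext = np.sort(extents)[::-1]
    return (round(float(np.prod(ext)), 9), round(float(ext[0]), 9))


def _min_rect_2d(pts2):
    """Rotating-calipers minimal-area rectangle of a 2D point set.

    Candidates are hull-edge-aligned orientations (one always attains the
    minimal area); ties on area break toward the shorter longest edge.
    Returns (extent_a, extent_b).
    """
    hull = ConvexHull(pts2)
    verts = pts2[hull.vertices]
    edges = np.diff(np.vstack([verts, verts[:1]]), axis=0)
    norms = np.hypot(edges[:, 0], edges[:, 1])
    u = edges[norms > 1e-12] / norms[norms > 1e-12, None]
    v = np.column_stack([-u[:, 1], u[:, 0]])
    proj_u = verts @ u.T          # (n_verts, n_orientations)
    proj_v = verts @ v.T
    ext_u = proj_u.max(axis=0) - proj_u.min(axis=0)
    ext_v = proj_v.max(axis=0) - proj_v.min(axis=0)
    area = np.round(ext_u * ext_v, 9)
    longest = np.round(np.maximum(ext_u, ext_v), 9)
    i = np.lexsort((longest, area))[0]
    return float(ext_u[i]), float(ext_v[i])


def _obb_longest_edge(points):
    """Longest edge of an oriented bounding box of ``points``.

    The box minimizes volume (then the longest edge, for ties). Degenerate
    rank is handled explicitly: collinear point sets use the line extent,
    planar sets the exact edge-aligned minimal rectangle in their plane;
    full-rank sets search hull-face-aligned orientations (each face normal
    as one box axis, calipers in the face plane) plus the principal-axis
    orientation.
    """
    P = points - points.mean(axis=0)
    U, s, Vt = np.linalg.svd(P, full_matrices=False)
    tol = max(s[0], 1.0) * 1e-9
    rank = int((s > tol).sum())
    if rank <= 1:
        proj = P @ Vt[0]
        return float(proj.max() - proj.min())
    if rank == 2:
        pts2 = P @ Vt[:2].T
        ext = _min_rect_2d(pts2)
        return float(max(ext))
    best_key, best_long = None, None
    candidates = [Vt]  # principal axes as fallback orientation
    hull_pts = P
    try:
        hull = ConvexHull(P)
        hull_pts = P[hull.vertices]
        nrm = hull.equations[:, :3]
        nrm = nrm / np.linalg.norm(nrm, axis=1, keepdims=True)
        # drop exactly duplicated (anti)parallel normals; the rounding must
        # stay fine so the candidate set is rotation-equivariant in practice
        _, keep = np.unique(np.round(np.abs(nrm), 6), axis=0,
                            return_index=True)
        nrm = nrm[np.sort(keep)]
        a = np.tile(np.array([1.0, 0.0, 0.0]), (len(nrm), 1))
        a[np.abs(nrm[:, 0]) > 0.9] = [0.0, 1.0, 0.0]
        u = np.cross(nrm, a)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v = np.cross(nrm, u)
        candidates.extend(np.stack([u[i], v[i], nrm[i]])
                          for i in range(len(nrm)))
    except QhullError:  # nearly-degenerate full-rank sets
        pass
    for basis in candidates:
        proj = hull_pts @ basis.T
        try:
            ea, eb = _min_rect_2d(proj[:, :2])
        except (QhullError, TypeError):
            continue
        ext = np.array([ea, eb, proj[:, 2].max() - proj[:, 2].min()])
        key = _rect_key(ext)
        if best_key is None or key < best_key:
            best_key, best_long = key, float(np.sort(ext)[-1])
    if best_long is None:  # all candidates degenerate; fall back to PCA
        proj = P @ Vt.T
        best_long = float((proj.max(axis=0) - proj.min(axis=0)).max())
    return best_long


# ---------------------------------------------------------------------------
# per-cilium measures
# ---------------------------------------------------------------------------

def measure_cilium(points):
    """Measures for one trace: arc, chord, OBB length proxy, tortuosity."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("trace must be an (n >= 2, 3) point array")
    if not np.isfinite(pts).all():
        raise ValueError("non-finite coordinates in trace")
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    if (seg_len < 1e-12).any():
        raise ValueError("consecutive duplicate points in trace")
    arc = float(seg_len.sum())
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    proxy = _obb_longest_edge(pts)
    if chord < 1e-12:
        raise ValueError("degenerate trace: endpoints coincide")
    return CiliumMeasures(arc, chord, proxy, arc / chord)


def _segment_distance(p1, p2, q1, q2):
    """Minimal distance between segments [p1,p2] and [q1,q2]."""
    d1, d2, r = p2 - p1, q2 - q1, p1 - q1
    a, e, f = d1 @ d1, d2 @ d2, d2 @ r
    c = d1 @ r
    b = d1 @ d2
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0, 1) if denom > 1e-15 else 0.0
    t = (b * s + f) / e if e > 1e-15 else 0.0
    if t < 0:
        t, s = 0.0, np.clip(-c / a, 0, 1) if a > 1e-15 else 0.0
    elif t > 1:
        t, s = 1.0, np.clip((b - c) / a, 0, 1) if a > 1e-15 else 0.0
    return float(np.linalg.norm(p1 + s * d1 - (q1 + t * d2)))


def _has_self_proximal_loop(points, radius, min_contour_gap=1.0):
    """True if the trace returns within ``radius`` um of itself.

    Only segment pairs separated by more than ``min_contour_gap`` um along
    the contour are compared, so locally smooth curvature does not count as
    a loop. Pairwise segment distances follow the standard clamped
    closest-point construction, vectorized over all admissible pairs.
    """
    d = np.diff(points, axis=0)
    seg_len = np.linalg.norm(d, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    m = len(d)
    i, j = np.triu_indices(m, k=2)
    keep = (cum[j] - cum[i + 1]) > min_contour_gap
    i, j = i[keep], j[keep]
    if i.size == 0:
        return False
    p1, d1 = points[i], d[i]
    q1, d2 = points[j], d[j]
    r = p1 - q1
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)
    denom = a * e - b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 1e-15,
                     np.clip((b * f - c * e) / np.where(denom > 1e-15,
                                                        denom, 1.0), 0, 1),
                     0.0)
        t = (b * s + f) / e
        s = np.where(t < 0, np.clip(-c / a, 0, 1),
                     np.where(t > 1, np.clip((b - c) / a, 0, 1), s))
        t = np.clip(t, 0, 1)
    gap = p1 + s[:, None] * d1 - (q1 + t[:, None] * d2)
    return bool((np.linalg.norm(gap, axis=1) < radius).any())


def classify_morphology(measures, points=None, t_straight=1.05,
                        t_contorted=1.5, loop_radius=0.2):
    """Assign straight / bent / contorted from explicit rules.

    straight: tortuosity < t_straight; contorted: tortuosity >= t_contorted,
    or (when the trace is given) the trace comes back within ``loop_radius``
    um of a point more than 1 um away along its own contour (a self-proximal
    loop); otherwise bent. Boundaries are half-open: tortuosity exactly
    t_straight is bent.
    """
    if measures.tortuosity < t_straight:
        return "straight"
    if measures.tortuosity >= t_contorted:
        return "contorted"
    if points is not None and _has_self_proximal_loop(
            np.asarray(points, float), loop_radius):
        return "contorted"
    return "bent"


def measure_table(traces, t_straight=1.05, t_contorted=1.5, loop_radius=0.2):
    """Per-cilium measures + class for a long-format trace table."""
    rows = []
    for cid, sub in traces.groupby("cilium_id", sort=True):
        sub = sub.sort_values("point_index")
        pts = sub[["x", "y", "z"]].to_numpy(dtype=float)
        m = measure_cilium(pts)
        cls = classify_morphology(m, pts, t_straight, t_contorted,
                                  loop_radius)
        rows.append({
            "cilium_id": cid,
            "mouse_id": sub["mouse_id"].iloc[0],
            "genotype": sub["genotype"].iloc[0],
            "arc_length": m.arc_length,
            "end_to_end": m.end_to_end,
            "length_proxy": m.length_proxy,
            "tortuosity": m.tortuosity,
            "morphology": cls,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def compare_groups(measures, value="length_proxy"):
    """Distributional comparison of genotype groups.

    Two-sample KS on pooled per-cilium lengths (exact p below 25 per group,
    asymptotic otherwise; exactly two genotypes required for KS), one-way
    ANOVA of length by genotype with both cilium and mouse as the unit of
    analysis, per-mouse mean lengths, and per-genotype morphology-class
    proportions.
    """
    groups = sorted(measures["genotype"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two genotypes")
    samples = [measures.loc[measures["genotype"] == g, value].to_numpy()
               for g in groups]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each genotype needs at least two cilia")
    if len(groups) == 2:
        method = "exact" if min(map(len, samples)) < 25 else "asymp"
        ks = ks_2samp(samples[0], samples[1], method=method)
        ks_d, ks_p = float(ks.statistic), float(ks.pvalue)
    else:
        ks_d, ks_p = np.nan, np.nan
    anova = f_oneway(*samples)
    mouse_means = (measures.groupby(["genotype", "mouse_id"])[value]
                   .mean().reset_index())
    mouse_samples = [
        mouse_means.loc[mouse_means["genotype"] == g, value].to_numpy()
        for g in groups]
    if all(len(s) >= 2 for s in mouse_samples):
        anova_m = f_oneway(*mouse_samples)
        f_m, p_m = float(anova_m.statistic), float(anova_m.pvalue)
    else:
        f_m, p_m = np.nan, np.nan
    props = (measures.groupby("genotype")["morphology"]
             .value_counts(normalize=True).unstack(fill_value=0.0)
             .reindex(columns=list(MORPHOLOGY_CLASSES), fill_value=0.0))
    return GroupComparison(
        tuple(groups), ks_d, ks_p, float(anova.statistic),
        float(anova.pvalue), f_m, p_m, mouse_means, props)
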