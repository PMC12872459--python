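"""Connective-field reconstruction and derived topographic metrics.

A fitted target's connective field on a source region is the eigenfunction
expansion ``w = Phi b*_band`` — a spatial map of how strongly each source
vertex contributes to explaining the target.  From it derive:

- the preferred topographic position (weight-averaged source coordinate),
- the sampling extent (median geodesic distance from the peak over vertices
  above half-maximum, within the peak's hemisphere),
- subfield proportions (rectified weight mass per body-part field),
- the full-vs-restricted source model comparison (delta R^2), and
- the basis-adequacy rule sizing K so sigma-wide Gaussian fields are
  reconstructable anywhere on the surface (min R^2 over centres >= floor).

Ridge weights can be negative; by default profiles are rectified (clipped at
zero) before weighted averaging, since a signed profile makes the
normalizing denominator ill-defined.  Raw mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .basis import LaplaceBasis
from .design import BandedDesign
from .mesh import TriangleMesh, geodesic_distances, geodesic_matrix
from .ridge import BandedRidgeFit, fit_banded_ridge, product_measure

__all__ = [
    "ConnectiveField",
    "MapProjection",
    "SubfieldProfile",
    "FieldModelComparison",
    "reconstruct_cf",
    "project_to_map",
    "sampling_extent",
    "subfield_proportions",
    "restricted_model_compare",
    "adequacy_k",
]


@dataclass
class ConnectiveField:
    """Spatial weight profile of one target on one source band."""

    weights: np.ndarray
    band: str
    target_id: Optional[object] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if not np.isfinite(self.weights).all():
            raise ValueError("connective-field weights must be finite")


@dataclass
class MapProjection:
    """Preferred topographic coordinate and supporting weight mass."""

    preferred_coordinate: Union[float, np.ndarray]
    weight_mass: float
    flagged: bool = False


@dataclass
class SubfieldProfile:
    """Per-field fractions of the (rectified) connective-field mass."""

    proportions: Dict[str, float]
    flagged: bool = False


@dataclass
class FieldModelComparison:
    """Full-source versus best restricted-source generalization."""

    delta_r2: np.ndarray          # (n_targets,) full minus best restricted
    best_field: List[str]
    full_r2: np.ndarray
    restricted_r2: Dict[str, np.ndarray]


def reconstruct_cf(fit: BandedRidgeFit,
                   bases: Union[LaplaceBasis, Sequence[LaplaceBasis]],
                   band: str, target: int = 0,
                   design: Optional[BandedDesign] = None) -> ConnectiveField:
    """Expand a target's band coefficients into source-vertex weights.

    ``bases`` is the basis of the band's single block, or the per-block
    (per-hemisphere) bases in design order; block reconstructions are
    concatenated.

    By default the weights are ``Phi b*`` — importance of each source
    vertex in the standardized-regressor space the model was fit in.  When
    the fitted ``design`` is supplied, each coefficient is first divided by
    its column's training s.d., undoing the z-scoring so the profile is in
    source-signal units (needed when comparing against a generative
    ground-truth profile).
    """
    if band not in fit.band_slices:
        raise ValueError(f"band {band!r} absent from fit")
    if isinstance(bases, LaplaceBasis):
        bases = [bases]
    b = fit.coefficients[fit.band_slices[band], target]
    if design is not None:
        b = b / design.col_std[design.band_slices[band]]
    ks = [basis.k for basis in bases]
    if sum(ks) != b.size:
        raise ValueError(
            f"band {band!r} has {b.size} coefficients, bases supply {sum(ks)}")
    parts, start = [], 0
    for basis in bases:
        parts.append(basis.eigenfunctions @ b[start:start + basis.k])
        start += basis.k
    return ConnectiveField(np.concatenate(parts), band=band,
                           target_id=None if fit.target_ids is None
                           else fit.target_ids[target])


def project_to_map(cf: ConnectiveField, source_map: np.ndarray,
                   rectify: bool = True, mass_floor: float = 1e-8) -> MapProjection:
    """Weight-averaged source coordinate: the preferred topographic position.

    ``preferred = sum_v w+_v m_v / sum_v w+_v`` with ``w+ = max(w, 0)`` when
    rectifying (default).  With rectification the projection is bounded by
    the source map's range.  A profile whose (rectified) mass falls below
    ``mass_floor`` has no defined preference and is flagged (NaN).
    """
    m = np.asarray(source_map, dtype=float)
    if m.shape[0] != cf.weights.size:
        raise ValueError("source map length must match the connective field")
    w = np.clip(cf.weights, 0.0, None) if rectify else cf.weights
    mass = float(w.sum())
    if abs(mass) < mass_floor:
        nan = np.nan if m.ndim == 1 else np.full(m.shape[1], np.nan)
        return MapProjection(nan, weight_mass=mass, flagged=True)
    return MapProjection(w @ m / mass, weight_mass=mass)


def sampling_extent(cf: ConnectiveField, mesh: TriangleMesh) -> float:
    """Median geodesic distance (mm) from the CF peak over half-max vertices.

    The peak is the maximum weight (ties broken toward the lowest vertex
    index); the support set is every same-hemisphere vertex with weight at
    least half the peak (hemispheres are not contiguous surfaces, so the
    opposite hemisphere never enters).  Returns NaN when no positive peak
    exists.
    """
    w = cf.weights
    if w.size != mesh.n_vertices:
        raise ValueError("connective field does not match the mesh")
    peak = int(np.argmax(w))
    if w[peak] <= 0:
        return float("nan")
    support = w >= w[peak] / 2.0
    if mesh.hemisphere is not None:
        support &= mesh.hemisphere == mesh.hemisphere[peak]
    d = geodesic_distances(mesh, [peak]).distances
    return float(np.median(d[support]))


def subfield_proportions(cf: ConnectiveField,
                         fields: Mapping[str, Sequence[int]],
                         rectify: bool = True) -> SubfieldProfile:
    """Fraction of (rectified) weight mass inside each source subfield.

    ``fields`` must partition the source vertices.  All-zero rectified mass
    yields a flagged, NaN profile.
    """
    n = cf.weights.size
    seen = np.concatenate([np.asarray(v, dtype=np.int64) for v in fields.values()])
    if len(seen) != n or len(np.unique(seen)) != n or seen.min() < 0 or seen.max() >= n:
        raise ValueError("fields must partition the source vertices")
    w = np.clip(cf.weights, 0.0, None) if rectify else cf.weights
    total = w.sum()
    if total <= 0:
        return SubfieldProfile({k: float("nan") for k in fields}, flagged=True)
    return SubfieldProfile(
        {k: float(w[np.asarray(v, dtype=np.int64)].sum() / total)
         for k, v in fields.items()})


def restricted_model_compare(full_design: BandedDesign,
                             restricted_designs: Mapping[str, BandedDesign],
                             y_train: np.ndarray, y_test: np.ndarray,
                             band: Optional[str] = None,
                             lambda_grid=None) -> FieldModelComparison:
    """Delta R^2 of the full source model over the best restricted model.

    Each restricted design replaces the full source with one subfield (its
    own, smaller basis) and is fit with the identical leave-one-run-out
    protocol.  The compared quantity is the test-set band share R~^2 of
    ``band`` (or the total R^2 for single-band designs).  Positive delta
    favours the continuous full-source model.
    """
    for name, d in restricted_designs.items():
        if list(d.run_lengths) != list(full_design.run_lengths):
            raise ValueError(f"restricted design {name!r} has different CV folds")

    def _score(design: BandedDesign, use_band: Optional[str]) -> np.ndarray:
        fit = fit_banded_ridge(design, y_train, lambda_grid=lambda_grid)
        part = product_measure(fit, design, y_test, dataset="test")
        if use_band is not None and use_band in part.r2_band:
            return part.r2_band[use_band]
        return part.r2_total

    full_r2 = _score(full_design, band)
    restricted = {name: _score(d, band if band in d.band_slices else None)
                  for name, d in restricted_designs.items()}
    names = list(restricted)
    stacked = np.stack([restricted[n] for n in names])
    best_idx = stacked.argmax(axis=0)
    best_r2 = stacked.max(axis=0)
    return FieldModelComparison(
        delta_r2=full_r2 - best_r2,
        best_field=[names[i] for i in best_idx],
        full_r2=full_r2,
        restricted_r2=restricted,
    )


def adequacy_k(mesh: TriangleMesh, sigma_mm: float = 4.0,
               r2_floor: float = 0.98, k_max: Optional[int] = None,
               basis: Optional[LaplaceBasis] = None,
               gdist: Optional[np.ndarray] = None) -> Tuple[int, np.ndarray]:
    """Smallest K whose truncated basis reconstructs sigma-wide Gaussians.

    For every vertex, a geodesic Gaussian field of s.d. ``sigma_mm`` centred
    there is least-squares projected onto the first K eigenfunctions
    (constant mode included); the adequacy criterion is that the minimum R^2
    over centres reaches ``r2_floor``.

    Returns ``(K, min_r2_curve)`` where ``min_r2_curve[k-1]`` is the minimum
    R^2 using k modes.  If the floor is unreachable at ``k_max`` the curve is
    returned with ``K = -1``.
    """
    from .basis import compute_basis  # local import avoids cycle at module load

    n = mesh.n_vertices
    if k_max is None:
        k_max = min(n - 2, 200)
    if basis is None:
        basis = compute_basis(mesh, k_max, drop_constant=False)
    phi = basis.eigenfunctions[:, :k_max]
    if gdist is None:
        gdist = geodesic_matrix(mesh)

    w = np.exp(-gdist**2 / (2.0 * sigma_mm**2))  # columns: field per centre
    # Nested least-squares spans via QR: Q[:, :k] spans the first k modes.
    q, _ = np.linalg.qr(phi)
    c = q.T @ w                                   # (k_max, n)
    cum = np.cumsum(c**2, axis=0)                 # explained sum of squares
    ss_w = (w ** 2).sum(axis=0)
    resid = np.maximum(ss_w[None, :] - cum, 0.0)  # residual SS after k modes
    # R^2 relative to the field's total energy: the fraction of the profile
    # captured by the truncated expansion (a constant-mode-only basis thus
    # reconstructs a constant field perfectly).
    r2 = 1.0 - resid / ss_w[None, :]
    min_curve = r2.min(axis=1)
    ok = np.flatnonzero(min_curve >= r2_floor)
    k = int(ok[0]) + 1 if ok.size else -1
    return k, min_curve
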