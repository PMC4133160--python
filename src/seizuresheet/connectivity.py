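"""Three-type mesoscopic connectivity: dense local Gaussian connections,
local excitatory-to-inhibitory connections, and remote patchy
excitatory connections, plus matrix assembly, statistics and
microincision editing.

Connection types
----------------
* local E->E: every ordered pair within a hard cutoff radius connects
  independently with probability ``exp(-d^2 / (2 sigma^2))``.
* local E->I: same sampler and parameters, independent random stream.
* remote E->E: each macrocolumn owns a few circular "patches" of units
  drawn within a maximal distance of its center, sharing some patches
  with one direct neighbour; every minicolumn sends a capped number of
  connections to units of its macrocolumn's patch pool.

All weights are stored non-negative; inhibitory sign is applied in the
drift, not in the matrices.  The I->E and I->I couplings act only within
a minicolumn, so those matrices are diagonal (no long-range inhibition).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .geometry import SheetGeometry, build_geometry
from .params import UnitParams

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ConnectivityParams:
    """Parameters of the connection generator.

    ``w_self_e``/``w_self_ei`` are the within-unit (diagonal) E->E and
    E->I couplings placed on the matrix diagonals; they equal the unit's
    ``c_ee``/``c_ei`` so that an isolated sheet unit reduces exactly to
    the single-unit model.
    """

    sigma_um: float = 170.0
    local_radius_um: float = 510.0
    n_patches_per_macro: int = 3
    patch_radius_units: int = 5
    max_patch_distance_um: float = 2500.0
    n_out_remote: int = 20
    n_shared_patches: int = 1
    w_local: float = 0.08463
    w_remote: float = 0.10417
    w_local_ei: float = 0.24683
    w_self_e: float = 12.0
    w_self_ei: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma_um <= 0 or self.local_radius_um <= 0:
            raise ValueError("sigma_um and local_radius_um must be positive")
        for name in ("n_patches_per_macro", "patch_radius_units", "n_out_remote", "n_shared_patches"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_shared_patches > self.n_patches_per_macro:
            raise ValueError("cannot share more patches than are owned")
        if self.max_patch_distance_um < self.patch_radius_units:
            raise ValueError("max_patch_distance_um must exceed the patch radius")


@dataclasses.dataclass
class PatchLayout:
    """Remote-patch bookkeeping: per-macrocolumn patch centers and members."""

    centers: dict[int, list[int]]          # macro index -> patch center units
    members: dict[int, np.ndarray]         # patch center unit -> member units
    sharing: dict[int, int]                # macro index -> neighbour macro shared with

    def pool(self, macro_index: int) -> np.ndarray:
        """Union of member units over the macrocolumn's patches."""
        parts = [self.members[c] for c in self.centers[macro_index]]
        return np.unique(np.concatenate(parts)) if parts else np.empty(0, dtype=int)

    def to_table(self) -> "np.ndarray":
        rows = []
        for macro, ctrs in sorted(self.centers.items()):
            for pid, c in enumerate(ctrs):
                rows.append((macro, pid, c, ",".join(map(str, self.members[c]))))
        return rows


@dataclasses.dataclass
class ConnectivityModel:
    """Assembled sparse coupling matrices over sheet units.

    ``w_ee``/``w_ei`` carry off-diagonal network terms plus within-unit
    diagonals; ``w_ie``/``w_ii`` are strictly diagonal.
    """

    w_ee: sp.csr_matrix
    w_ei: sp.csr_matrix
    w_ie: sp.csr_matrix
    w_ii: sp.csr_matrix
    geometry: SheetGeometry
    provenance: dict = dataclasses.field(default_factory=dict)
    patch_layout: PatchLayout | None = None

    def copy(self) -> "ConnectivityModel":
        return ConnectivityModel(
            self.w_ee.copy(), self.w_ei.copy(), self.w_ie.copy(), self.w_ii.copy(),
            self.geometry, dict(self.provenance), self.patch_layout,
        )


# ---------------------------------------------------------------------------
# samplers


def _local_offsets(geom: SheetGeometry, radius_um: float):
    rad = int(radius_um // geom.pitch_um) + 1
    out = []
    for dx in range(-rad, rad + 1):
        for dy in range(-rad, rad + 1):
            if (dx, dy) == (0, 0):
                continue
            d = geom.pitch_um * float(np.hypot(dx, dy))
            if d <= radius_um:
                out.append((dx, dy, d))
    return out


def sample_local_connections(
    geom: SheetGeometry, sigma_um: float, radius_um: float, seed: int
) -> sp.csr_matrix:
    """Boolean adjacency of local connections.

    Each ordered pair (i -> j) with distance ``d <= radius_um`` connects
    independently with probability ``exp(-d^2/(2 sigma^2))``; no
    self-connections; nothing beyond the cutoff.  Fully determined by
    ``seed``.
    """
    if sigma_um <= 0 or radius_um <= 0:
        raise ValueError("sigma_um and radius_um must be positive")
    rng = np.random.default_rng(seed)
    rows, cols = geom.rows, geom.cols
    n = geom.n_units
    src_acc, dst_acc = [], []
    for dx, dy, d in _local_offsets(geom, radius_um):
        p = float(np.exp(-(d * d) / (2.0 * sigma_um * sigma_um)))
        mask = rng.random(n) < p
        src = np.nonzero(mask)[0]
        tr, tc = rows[src] + dx, cols[src] + dy
        if geom.boundary == "torus":
            tr %= geom.n_rows
            tc %= geom.n_cols
        else:
            ok = (tr >= 0) & (tr < geom.n_rows) & (tc >= 0) & (tc < geom.n_cols)
            src, tr, tc = src[ok], tr[ok], tc[ok]
        src_acc.append(src)
        dst_acc.append(tr * geom.n_cols + tc)
    src = np.concatenate(src_acc) if src_acc else np.empty(0, dtype=int)
    dst = np.concatenate(dst_acc) if dst_acc else np.empty(0, dtype=int)
    return sp.csr_matrix((np.ones(len(src)), (src, dst)), shape=(n, n))


def sample_remote_patches(
    geom: SheetGeometry, params: ConnectivityParams, seed: int
) -> tuple[PatchLayout, sp.csr_matrix]:
    """Remote patchy adjacency and its :class:`PatchLayout`.

    Patch centers are drawn uniformly among units within
    ``max_patch_distance_um`` of each macrocolumn center; the first
    ``n_shared_patches`` are replaced by patches of one uniformly chosen
    direct neighbour (taken from the neighbour's own draw, so sharing can
    carry a patch beyond the distance bound).  Each minicolumn then draws
    ``n_out_remote`` targets uniformly with replacement from its
    macrocolumn's patch pool; duplicates collapse, so the out-degree is
    capped at ``n_out_remote``.
    """
    rng = np.random.default_rng(seed)
    n = geom.n_units

    own: dict[int, list[int]] = {}
    for m in range(geom.n_macros):
        ctr = geom.macro_center_unit(m)
        cand = np.nonzero(geom.distances_from(ctr) <= params.max_patch_distance_um)[0]
        if len(cand) < params.n_patches_per_macro:
            raise ValueError(
                "geometry too small for max_patch_distance_um: only "
                f"{len(cand)} candidate units near macrocolumn {m}"
            )
        own[m] = list(rng.choice(cand, params.n_patches_per_macro, replace=False))

    centers: dict[int, list[int]] = {}
    sharing: dict[int, int] = {}
    for m in range(geom.n_macros):
        mr, mc = divmod(m, geom.macro_cols)
        nb = [(mr - 1, mc), (mr + 1, mc), (mr, mc - 1), (mr, mc + 1)]
        if geom.boundary == "torus":
            nb = [((r % geom.macro_rows) * geom.macro_cols + c % geom.macro_cols) for r, c in nb]
        else:
            nb = [
                r * geom.macro_cols + c
                for r, c in nb
                if 0 <= r < geom.macro_rows and 0 <= c < geom.macro_cols
            ]
        partner = int(nb[rng.integers(len(nb))]) if nb else m
        sharing[m] = partner
        # share patches the partner retains in its own final layout (its
        # first n_shared slots are themselves replaced by shared patches)
        ns = params.n_shared_patches
        shared = own[partner][ns : 2 * ns]
        if len(shared) < ns:  # partner owns too few retained patches
            shared = own[partner][-ns:]
        centers[m] = shared + own[m][ns:]

    members = {
        c: geom.disc(c, params.patch_radius_units)
        for ctrs in centers.values()
        for c in ctrs
    }
    layout = PatchLayout(centers, members, sharing)

    src_acc, dst_acc = [], []
    macro_of = geom.macro_of_unit
    for m in range(geom.n_macros):
        pool = layout.pool(m)
        if len(pool) == 0:
            continue
        units = np.nonzero(macro_of == m)[0]
        draws = rng.choice(pool, size=(len(units), params.n_out_remote), replace=True)
        for u, row in zip(units, draws):
            tgt = np.unique(row)
            tgt = tgt[tgt != u]
            src_acc.append(np.full(len(tgt), u))
            dst_acc.append(tgt)
    src = np.concatenate(src_acc) if src_acc else np.empty(0, dtype=int)
    dst = np.concatenate(dst_acc) if dst_acc else np.empty(0, dtype=int)
    adj = sp.csr_matrix((np.ones(len(src)), (src, dst)), shape=(n, n))
    return layout, adj


# ---------------------------------------------------------------------------
# assembly


def assemble_weight_matrices(
    local_ee: sp.spmatrix,
    local_ei: sp.spmatrix,
    remote_ee: sp.spmatrix,
    unit_params: UnitParams,
    conn_params: ConnectivityParams,
    geometry: SheetGeometry,
    provenance: dict | None = None,
    patch_layout: PatchLayout | None = None,
) -> ConnectivityModel:
    """Weighted coupling matrices from boolean adjacencies.

    Overlapping local and remote pairs sum their weights.  The realized
    local:remote connection-count ratio is logged and recorded in the
    model provenance.
    """
    n = geometry.n_units
    for m in (local_ee, local_ei, remote_ee):
        if m.shape != (n, n):
            raise ValueError("adjacency shape does not match geometry")
    eye = sp.identity(n, format="csr")
    w_ee = (conn_params.w_local * local_ee + conn_params.w_remote * remote_ee
            + conn_params.w_self_e * eye).tocsr()
    w_ei = (conn_params.w_local_ei * local_ei + conn_params.w_self_ei * eye).tocsr()
    w_ie = (unit_params.c_ie * eye).tocsr()
    w_ii = (unit_params.c_ii * eye).tocsr()
    n_local = int(local_ee.nnz)
    n_remote = int(remote_ee.nnz)
    ratio = n_local / n_remote if n_remote else float("inf")
    logger.info(
        "assembled connectivity: %d local E->E, %d remote E->E (ratio %.2f), %d local E->I",
        n_local, n_remote, ratio, int(local_ei.nnz),
    )
    prov = dict(provenance or {})
    prov.update(
        {
            "n_local_ee": n_local,
            "n_remote_ee": n_remote,
            "n_local_ei": int(local_ei.nnz),
            "local_remote_ratio": ratio,
            "connectivity_params": dataclasses.asdict(conn_params),
        }
    )
    return ConnectivityModel(w_ee, w_ei, w_ie, w_ii, geometry, prov, patch_layout)


def build_connectivity(
    geom: SheetGeometry,
    unit_params: UnitParams,
    conn_params: ConnectivityParams,
    seed: int,
) -> ConnectivityModel:
    """Convenience wrapper: sample all three adjacencies and assemble.

    Independent seed streams are derived from ``seed`` for the local E->E,
    local E->I and remote samplers.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    s_ee, s_ei, s_rem = (int(s.generate_state(1)[0]) for s in ss)
    local_ee = sample_local_connections(geom, conn_params.sigma_um, conn_params.local_radius_um, s_ee)
    local_ei = sample_local_connections(geom, conn_params.sigma_um, conn_params.local_radius_um, s_ei)
    layout, remote_ee = sample_remote_patches(geom, conn_params, s_rem)
    return assemble_weight_matrices(
        local_ee, local_ei, remote_ee, unit_params, conn_params, geom,
        provenance={"seed": seed}, patch_layout=layout,
    )


# ---------------------------------------------------------------------------
# statistics


def _offdiag_coo(mat: sp.spmatrix) -> sp.coo_matrix:
    m = mat.tocoo()
    keep = m.row != m.col
    return sp.coo_matrix((m.data[keep], (m.row[keep], m.col[keep])), shape=m.shape)


def connection_statistics(model: ConnectivityModel) -> dict:
    """Degree and connection-distance histograms per connection type.

    Distances are computed under the model's geometry and binned at one
    pitch; degree histograms are raw counts by degree.
    """
    geom = model.geometry
    w_local = model.provenance.get("connectivity_params", {}).get("w_local")
    out: dict[str, dict] = {}
    ee = _offdiag_coo(model.w_ee)
    # split E->E into local and remote by weight when possible
    groups: dict[str, sp.coo_matrix] = {}
    if w_local is not None and ee.nnz:
        w_remote = model.provenance["connectivity_params"]["w_remote"]
        is_loc = np.isclose(ee.data, w_local) | np.isclose(ee.data, w_local + w_remote)
        is_rem = np.isclose(ee.data, w_remote) | np.isclose(ee.data, w_local + w_remote)
        groups["local_ee"] = sp.coo_matrix((np.ones(is_loc.sum()), (ee.row[is_loc], ee.col[is_loc])), shape=ee.shape)
        groups["remote_ee"] = sp.coo_matrix((np.ones(is_rem.sum()), (ee.row[is_rem], ee.col[is_rem])), shape=ee.shape)
    else:
        groups["ee"] = ee
    groups["local_ei"] = _offdiag_coo(model.w_ei)

    for name, g in groups.items():
        dists = geom.distance_um(g.row, g.col) if g.nnz else np.empty(0)
        max_d = dists.max() if g.nnz else geom.pitch_um
        bins = np.arange(0, max_d + 2 * geom.pitch_um, geom.pitch_um)
        dist_hist, dist_edges = np.histogram(dists, bins=bins)
        out_deg = np.bincount(g.row, minlength=geom.n_units)
        in_deg = np.bincount(g.col, minlength=geom.n_units)
        out[name] = {
            "n_connections": int(g.nnz),
            "out_degree": out_deg,
            "in_degree": in_deg,
            "distance_hist": dist_hist,
            "distance_edges": dist_edges,
        }
    return out


# ---------------------------------------------------------------------------
# microincision


def _strict_cross(p0, p1, q0, q1) -> np.ndarray:
    """Vectorized strict (open-segment) crossing test.

    ``p0``/``p1``: (n,2) chord endpoints; ``q0``/``q1``: cut endpoints.
    Touching an endpoint does not count as a crossing.
    """
    def orient(a, b, c):
        return (b[..., 0] - a[..., 0]) * (c[..., 1] - a[..., 1]) - (
            b[..., 1] - a[..., 1]
        ) * (c[..., 0] - a[..., 0])

    d1 = orient(q0, q1, p0)
    d2 = orient(q0, q1, p1)
    d3 = orient(p0, p1, q0)
    d4 = orient(p0, p1, q1)
    return (d1 * d2 < 0) & (d3 * d4 < 0)


def apply_microincision(model: ConnectivityModel, cuts) -> ConnectivityModel:
    """Remove all off-diagonal connections whose straight chord between
    unit centers crosses any cut segment.

    ``cuts``: iterable of ((x0, y0), (x1, y1)) segments in sheet
    coordinates (um).  On a torus the chord uses the minimal-image
    displacement.  Diagonal (within-unit) couplings are untouched.
    """
    geom = model.geometry
    cuts = [np.asarray(c, dtype=float) for c in cuts]
    for c in cuts:
        if c.shape != (2, 2) or not np.all(np.isfinite(c)):
            raise ValueError("each cut must be a finite 2x2 array ((x0,y0),(x1,y1))")
        span_x = geom.n_cols * geom.pitch_um
        span_y = geom.n_rows * geom.pitch_um
        if np.any(c[:, 0] < -geom.pitch_um) or np.any(c[:, 0] > span_x) or \
           np.any(c[:, 1] < -geom.pitch_um) or np.any(c[:, 1] > span_y):
            raise ValueError("cut segment outside sheet bounds")

    def filter_matrix(mat: sp.csr_matrix) -> sp.csr_matrix:
        m = mat.tocoo()
        off = m.row != m.col
        if not off.any():
            return mat
        r, c, d = m.row[off], m.col[off], m.data[off]
        x0, y0 = geom.position_um(r)
        dr, dc = geom.displacement(r, c)
        x1 = x0 + dc * geom.pitch_um
        y1 = y0 + dr * geom.pitch_um
        p0 = np.stack([x0, y0], axis=1)
        p1 = np.stack([x1, y1], axis=1)
        cut_mask = np.zeros(len(r), dtype=bool)
        for seg in cuts:
            cut_mask |= _strict_cross(p0, p1, seg[0], seg[1])
        keep = ~cut_mask
        diag = m.row == m.col
        rows = np.concatenate([r[keep], m.row[diag]])
        colz = np.concatenate([c[keep], m.col[diag]])
        data = np.concatenate([d[keep], m.data[diag]])
        return sp.csr_matrix((data, (rows, colz)), shape=m.shape)

    out = model.copy()
    out.w_ee = filter_matrix(out.w_ee)
    out.w_ei = filter_matrix(out.w_ei)
    # w_ie / w_ii are diagonal; nothing to cut
    out.provenance = dict(out.provenance)
    out.provenance["microincision_cuts"] = [c.tolist() for c in cuts]
    return out


# ---------------------------------------------------------------------------
# persistence


def export_model(model: ConnectivityModel, directory: str | Path) -> None:
    """Write matrices as MatrixMarket files plus a JSON metadata sidecar
    and, when present, the patch layout as a tab-separated table."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name in ("w_ee", "w_ei", "w_ie", "w_ii"):
        mmwrite(str(d / f"{name}.mtx"), getattr(model, name))
    g = model.geometry
    meta = {
        "geometry": {
            "n_rows": g.n_rows, "n_cols": g.n_cols, "macro_edge": g.macro_edge,
            "pitch_um": g.pitch_um, "boundary": g.boundary,
        },
        "provenance": model.provenance,
    }
    (d / "metadata.json").write_text(json.dumps(meta, indent=2, default=str))
    if model.patch_layout is not None:
        lines = ["patch_id\towner_macro\tcenter\tmembers"]
        pid = 0
        for macro, ctrs in sorted(model.patch_layout.centers.items()):
            for c in ctrs:
                mem = ",".join(map(str, model.patch_layout.members[c]))
                lines.append(f"{pid}\t{macro}\t{c}\t{mem}")
                pid += 1
        (d / "patches.tsv").write_text("\n".join(lines) + "\n")


def import_model(directory: str | Path) -> ConnectivityModel:
    d = Path(directory)
    meta = json.loads((d / "metadata.json").read_text())
    geom = build_geometry(**meta["geometry"])
    mats = {name: sp.csr_matrix(mmread(str(d / f"{name}.mtx"))) for name in ("w_ee", "w_ei", "w_ie", "w_ii")}
    return ConnectivityModel(geometry=geom, provenance=meta.get("provenance", {}), **mats)
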