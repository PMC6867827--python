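"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates single cardiomyocyte-like cells imaged by smFISH:
diffraction-limited transcript spots placed in the cytoplasm with a
perinuclear density bias, multi-copy clusters, a controlled colocalized
fraction between two species (optionally extended to planted triples with a
protein channel), a single-molecule intensity with multiplicative lognormal
noise, Poisson-noise image rendering, qPCR Ct replicate tables with
condition fold-changes, and Boltzmann-gated voltage-clamp sweep families.

All randomness flows from a single integer seed through a
``numpy.random.Generator`` created at the top of each generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import CellGeometry, DEFAULT_PIXEL_SIZE_NM
from .ephys import SweepProtocol, SweepSet, boltzmann_iv

#: Default cluster-size mixture (fraction of detected particles containing
#: 1..6+ transcript copies).  Anchored at ~25% singles and ~20% in clusters
#: of six or more, the two fractions reported for the cardiac transcripts;
#: intermediate classes decay smoothly (unreported in the source data).
CLUSTER_DIST_DEFAULT = {1: 0.25, 2: 0.20, 3: 0.15, 4: 0.12, 5: 0.08, 6: 0.20}


class PlacementError(RuntimeError):
    """Requested spot count cannot be placed in the available area."""


@dataclass
class GroundTruth:
    """Bookkeeping emitted alongside simulated spot tables.

    ``true_coloc_pairs`` / ``true_triples`` reference ``spot_id`` values in
    ``true_spots``.
    """

    true_spots: pd.DataFrame
    true_single_intensity: float
    true_coloc_pairs: list
    true_coloc_fraction: float
    seed: int
    true_triples: list = field(default_factory=list)

    def __post_init__(self):
        ids = set(self.true_spots["spot_id"])
        for a, b in self.true_coloc_pairs:
            if a not in ids or b not in ids:
                raise ValueError("colocalized pair references an unknown spot id")
        if not 0.0 <= self.true_coloc_fraction <= 1.0:
            raise ValueError("true_coloc_fraction must lie in [0, 1]")

    def counts_per_cell(self) -> pd.DataFrame:
        """Ground-truth particle and copy counts per (cell, channel)."""
        g = self.true_spots.groupby(["cell_id", "channel"])
        out = g.agg(spots=("spot_id", "size"), copies=("copies", "sum")).reset_index()
        return out

    def pairs_per_cell(self) -> pd.Series:
        if not self.true_coloc_pairs:
            return pd.Series(dtype=int)
        lookup = self.true_spots.set_index("spot_id")["cell_id"]
        cells = [lookup[a] for a, _ in self.true_coloc_pairs]
        return pd.Series(cells).value_counts().sort_index()


# ---------------------------------------------------------------------------
# Spot fields
# ---------------------------------------------------------------------------


class _Placer:
    """Samples sub-pixel spot positions from the cytoplasm.

    Placement probability decays with distance to the nucleus as
    ``exp(-dist / lambda)``; ``lambda = inf`` gives uniform placement.
    """

    def __init__(self, geometry: CellGeometry, lambda_um: float):
        self.geometry = geometry
        rows, cols = np.nonzero(geometry.cytoplasm_mask)
        if rows.size == 0:
            raise PlacementError("cytoplasm mask is empty")
        self.rows, self.cols = rows, cols
        if np.isinf(lambda_um):
            self.cum = None
        else:
            dist = geometry.nucleus_distance_map_um()[rows, cols]
            w = np.exp(-dist / lambda_um)
            self.cum = np.cumsum(w)
            self.cum /= self.cum[-1]

    def draw(self, rng: np.random.Generator, n: int):
        """Return (x_nm, y_nm) arrays of n positions."""
        if self.cum is None:
            idx = rng.integers(0, self.rows.size, n)
        else:
            idx = np.searchsorted(self.cum, rng.random(n))
        px = self.geometry.pixel_size_nm
        x = (self.cols[idx] + rng.random(n)) * px
        y = (self.rows[idx] + rng.random(n)) * px
        return x, y

    def inside(self, x_nm: float, y_nm: float) -> bool:
        px = self.geometry.pixel_size_nm
        r, c = int(y_nm // px), int(x_nm // px)
        ny, nx = self.geometry.image_shape_px
        return 0 <= r < ny and 0 <= c < nx and bool(self.geometry.cytoplasm_mask[r, c])


def _lognormal_factor(rng, n, cv):
    if cv <= 0:
        return np.ones(n)
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=n)


def simulate_spot_field(
    geometry: CellGeometry,
    counts_per_species: dict,
    *,
    cluster_dist: dict | None = None,
    coloc_fraction: float = 0.0,
    coloc_distance_nm: float = DEFAULT_PIXEL_SIZE_NM,
    single_intensity: float = 1000.0,
    intensity_cv: float = 0.15,
    perinuclear_lambda_um: float = 10.0,
    n_cells: int = 1,
    species_pair: tuple | None = None,
    protein_species: str | None = None,
    triple_fraction: float = 0.0,
    count_correlation: float = 0.0,
    sigma_nm: float | None = None,
    seed: int = 0,
):
    """Simulate spot tables for one or more cells sharing a geometry.

    Parameters
    ----------
    counts_per_species : dict
        Species label -> spots per cell; an int places that exact count, a
        ``(low, high)`` tuple draws a per-cell count uniformly in the range
        (inclusive), spanning e.g. the ~5-200/cell range seen in cells.
    coloc_fraction : float
        Fraction of species-A spots given a species-B partner placed
        uniformly within a disc of radius ``coloc_distance_nm``.  The
        planted pair count per cell is ``round(fraction * n_A)`` exactly.
    triple_fraction : float
        Fraction of the planted A-B pairs that also receive a
        ``protein_species`` partner within the same distance.
    perinuclear_lambda_um : float
        Length scale of the perinuclear density bias; ``inf`` for uniform.
    count_correlation : float
        Correlation of the paired species' per-cell counts (Gaussian copula
        over the count ranges), emulating cells that express both
        transcripts in a roughly fixed ratio.  Only applies when both
        species of ``species_pair`` have ``(low, high)`` count ranges.
    sigma_nm : float
        Reported PSF-width per spot; defaults to one pixel.

    Returns
    -------
    (spots, truth) : (pandas.DataFrame, GroundTruth)
        Spot table with columns ``spot_id, cell_id, channel, x_nm, y_nm,
        z_nm, intensity, sigma_nm, copies``.
    """
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ValueError("coloc_fraction must lie in [0, 1]")
    cluster_dist = dict(cluster_dist or CLUSTER_DIST_DEFAULT)
    copies_vals = np.array(sorted(cluster_dist))
    copies_p = np.array([cluster_dist[c] for c in copies_vals], dtype=float)
    if not np.isclose(copies_p.sum(), 1.0):
        raise ValueError("cluster_dist probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    placer = _Placer(geometry, perinuclear_lambda_um)

    species = list(counts_per_species)
    if species_pair is None:
        species_pair = tuple(species[:2]) if len(species) >= 2 else None

    def resolve_count(spec):
        if np.isscalar(spec):
            return int(spec)
        lo, hi = spec
        return int(rng.integers(lo, hi + 1))

    max_placeable = int(geometry.cytoplasm_mask.sum())
    records = []
    pairs: list[tuple[int, int]] = []
    triples: list[tuple[int, int, int]] = []
    sigma = float(sigma_nm if sigma_nm is not None else geometry.pixel_size_nm)
    next_id = 0

    def add_spots(cell, channel, x, y):
        nonlocal next_id
        n = len(x)
        copies = rng.choice(copies_vals, size=n, p=copies_p)
        inten = copies * single_intensity * _lognormal_factor(rng, n, intensity_cv)
        ids = np.arange(next_id, next_id + n)
        next_id += n
        records.append(
            pd.DataFrame(
                {
                    "spot_id": ids,
                    "cell_id": cell,
                    "channel": channel,
                    "x_nm": x,
                    "y_nm": y,
                    "z_nm": 0.0,
                    "intensity": inten,
                    "sigma_nm": sigma,
                    "copies": copies,
                }
            )
        )
        return ids

    def place_partners(xa, ya):
        """Partner positions uniform in a disc around each anchor, kept in
        the cytoplasm (falls back to the anchor position when the whole
        neighbourhood is outside)."""
        xs, ys = np.empty(len(xa)), np.empty(len(xa))
        for i, (ax, ay) in enumerate(zip(xa, ya)):
            for _ in range(64):
                rad = coloc_distance_nm * np.sqrt(rng.random())
                ang = rng.random() * 2.0 * np.pi
                px_, py_ = ax + rad * np.cos(ang), ay + rad * np.sin(ang)
                if placer.inside(px_, py_):
                    xs[i], ys[i] = px_, py_
                    break
            else:
                xs[i], ys[i] = ax, ay
        return xs, ys

    def draw_cell_counts():
        counts = {}
        paired = (
            species_pair
            if (
                species_pair is not None
                and count_correlation != 0.0
                and not np.isscalar(counts_per_species[species_pair[0]])
                and not np.isscalar(counts_per_species[species_pair[1]])
            )
            else None
        )
        if paired is not None:
            rho = float(np.clip(count_correlation, -0.999, 0.999))
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]])
            from scipy.special import ndtr

            for sp, zi in zip(paired, z):
                lo, hi = counts_per_species[sp]
                u = ndtr(zi)
                counts[sp] = int(lo + np.floor(u * (hi - lo + 1)))
        for sp in species:
            if sp not in counts:
                counts[sp] = resolve_count(counts_per_species[sp])
        return counts

    for cell in range(n_cells):
        counts = draw_cell_counts()
        if sum(counts.values()) > max_placeable:
            raise PlacementError("requested spot count exceeds the placeable area")
        cell_pairs: list[tuple[int, int]] = []
        if species_pair is not None:
            sp_a, sp_b = species_pair
            n_a, n_b = counts[sp_a], counts[sp_b]
            n_pairs = int(round(coloc_fraction * n_a))
            if n_pairs > n_b:
                raise ValueError("coloc_fraction requires more partners than species B has")
            xa, ya = placer.draw(rng, n_a)
            ids_a = add_spots(cell, sp_a, xa, ya)
            xb_p, yb_p = place_partners(xa[:n_pairs], ya[:n_pairs])
            xb_f, yb_f = placer.draw(rng, n_b - n_pairs)
            ids_b = add_spots(
                cell, sp_b, np.concatenate([xb_p, xb_f]), np.concatenate([yb_p, yb_f])
            )
            cell_pairs = list(zip(ids_a[:n_pairs], ids_b[:n_pairs]))
            pairs.extend(cell_pairs)
            placed_b_ids = ids_b
            done = {sp_a, sp_b}
        else:
            done = set()
        for sp in species:
            if sp in done or sp == protein_species:
                continue
            x, y = placer.draw(rng, counts[sp])
            add_spots(cell, sp, x, y)
        if protein_species is not None and protein_species not in done:
            n_p = counts[protein_species]
            n_tr = int(round(triple_fraction * len(cell_pairs))) if species_pair else 0
            if n_tr > n_p:
                raise ValueError("triple_fraction requires more protein spots than available")
            anchors = cell_pairs[:n_tr]
            ax = np.array([xa[i] for i in range(n_tr)])
            ay = np.array([ya[i] for i in range(n_tr)])
            xp_t, yp_t = place_partners(ax, ay)
            xp_f, yp_f = placer.draw(rng, n_p - n_tr)
            ids_p = add_spots(
                cell,
                protein_species,
                np.concatenate([xp_t, xp_f]),
                np.concatenate([yp_t, yp_f]),
            )
            triples.extend(
                (a, b, p) for (a, b), p in zip(anchors, ids_p[:n_tr])
            )

    spots = pd.concat(records, ignore_index=True) if records else pd.DataFrame(
        columns=[
            "spot_id", "cell_id", "channel", "x_nm", "y_nm", "z_nm",
            "intensity", "sigma_nm", "copies",
        ]
    )
    spots.attrs["pixel_size_nm"] = geometry.pixel_size_nm
    truth = GroundTruth(
        true_spots=spots.copy(),
        true_single_intensity=single_intensity,
        true_coloc_pairs=pairs,
        true_coloc_fraction=coloc_fraction,
        seed=seed,
        true_triples=triples,
    )
    return spots, truth


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------


def _gauss_mass_1d(n, center_px, sigma_px, lo):
    """Pixel-integrated unit Gaussian over pixels lo..lo+n-1."""
    from scipy.special import erf

    edges = np.arange(lo, lo + n + 1, dtype=float)
    z = (edges - center_px) / (sigma_px * np.sqrt(2.0))
    cdf = 0.5 * (1.0 + erf(z))
    return np.diff(cdf)


def render_image(
    spot_table: pd.DataFrame,
    geometry: CellGeometry,
    *,
    psf_sigma_px: float = 1.0,
    photons_per_unit: float = 1.0,
    background: float = 0.0,
    noise: bool = True,
    n_planes: int = 1,
    psf_sigma_z_planes: float = 1.0,
    seed: int = 0,
):
    """Render a spot table to an image (2D) or stack (3D).

    Each spot contributes a pixel-integrated Gaussian whose total photon
    count is ``photons_per_unit * intensity``; a flat ``background`` is
    added and Poisson noise applied.  With ``noise=True`` the result is a
    16-bit unsigned array (the on-disk TIFF convention); with
    ``noise=False`` the noiseless float expectation is returned.
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be positive")
    ny, nx = geometry.image_shape_px
    px = geometry.pixel_size_nm
    nz = int(n_planes)
    img = np.full((nz, ny, nx), float(background))
    half = int(np.ceil(6.0 * psf_sigma_px))
    half_z = int(np.ceil(6.0 * psf_sigma_z_planes))
    for row in spot_table.itertuples():
        xc, yc = row.x_nm / px, row.y_nm / px
        if not (0 <= xc < nx and 0 <= yc < ny):
            raise ValueError(f"spot {row.spot_id} lies outside the image")
        photons = photons_per_unit * row.intensity
        cx, cy = int(np.floor(xc)), int(np.floor(yc))
        x0, x1 = max(0, cx - half), min(nx, cx + half + 1)
        y0, y1 = max(0, cy - half), min(ny, cy + half + 1)
        mx = _gauss_mass_1d(x1 - x0, xc, psf_sigma_px, x0)
        my = _gauss_mass_1d(y1 - y0, yc, psf_sigma_px, y0)
        if nz == 1:
            img[0, y0:y1, x0:x1] += photons * np.outer(my, mx)
        else:
            zc = row.z_nm / geometry.z_step_nm
            cz = int(np.floor(zc))
            z0, z1 = max(0, cz - half_z), min(nz, cz + half_z + 1)
            mz = _gauss_mass_1d(z1 - z0, zc, psf_sigma_z_planes, z0)
            img[z0:z1, y0:y1, x0:x1] += photons * (
                mz[:, None, None] * my[None, :, None] * mx[None, None, :]
            )
    if noise:
        rng = np.random.default_rng(seed)
        img = rng.poisson(img).astype(np.uint16)
    return img[0] if nz == 1 else img


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def simulate_qpcr(
    conditions,
    genes,
    fold_changes: dict,
    *,
    reference_gene: str = "ACTB",
    control_condition: str | None = None,
    ct_reference=20.0,
    n_bio: int = 6,
    n_tech: int = 3,
    noise_sd_ct: float = 0.2,
    sample_sd_ct: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a Ct table: ``Ct = ct_ref(gene) - log2(fold) + noise``.

    ``fold_changes`` maps either gene -> fold (applied to every non-control
    condition) or ``(condition, gene)`` -> fold.  The reference gene always
    has fold 1.  ``sample_sd_ct`` adds a shared offset per (sample,
    condition) RNA prep, which cancels in the within-sample normalization.

    Returns a frame with columns ``sample, condition, gene, ct``; ``sample``
    labels the biological replicate and technical replicates appear as
    repeated rows.
    """
    conditions = list(conditions)
    genes = list(genes)
    if reference_gene not in genes:
        raise ValueError(f"reference gene {reference_gene!r} missing from gene list")
    if n_bio < 2:
        raise ValueError("at least 2 biological replicates are required")
    control = conditions[0] if control_condition is None else control_condition
    if control not in conditions:
        raise ValueError(f"control condition {control!r} missing")

    def fold_for(cond, gene):
        if gene == reference_gene or cond == control:
            f = fold_changes.get((cond, gene), 1.0) if gene == reference_gene else 1.0
            if gene == reference_gene and f != 1.0:
                raise ValueError("reference gene fold change must be 1")
            return 1.0
        if (cond, gene) in fold_changes:
            return float(fold_changes[(cond, gene)])
        return float(fold_changes.get(gene, 1.0))

    base = (
        dict(ct_reference)
        if isinstance(ct_reference, dict)
        else {g: float(ct_reference) for g in genes}
    )
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_bio):
        sample = f"rep{b + 1}"
        for cond in conditions:
            offset = rng.normal(0.0, sample_sd_ct) if sample_sd_ct > 0 else 0.0
            for gene in genes:
                mean_ct = base[gene] - np.log2(fold_for(cond, gene)) + offset
                for _ in range(n_tech):
                    ct = mean_ct + (rng.normal(0.0, noise_sd_ct) if noise_sd_ct > 0 else 0.0)
                    rows.append((sample, cond, gene, ct))
    return pd.DataFrame(rows, columns=["sample", "condition", "gene", "ct"])


# ---------------------------------------------------------------------------
# Voltage-clamp sweeps
# ---------------------------------------------------------------------------


def simulate_sweeps(
    protocol: SweepProtocol,
    *,
    g_max_nS: float = 10.0,
    v_rev_mV: float = -88.0,
    v_half_mV: float = -20.0,
    k_mV: float = -7.0,
    tau_act_s: float = 0.3,
    tau_deact_s: float = 0.3,
    late_plateau_pA: float = 0.0,
    late_tau_s: float = np.inf,
    noise_sd_pA: float = 0.0,
    seed: int = 0,
) -> SweepSet:
    """Generate Boltzmann-gated current sweeps for a step protocol.

    During the step the current relaxes exponentially (time constant
    ``tau_act_s``; 0 for instantaneous gating) toward the steady state of
    the activation equation; the tail decays from the end-of-step activation
    level at the tail driving force.  An optional late component (plateau
    with time constant ``late_tau_s``, ``inf`` for a rectangle) is added
    during the step, emulating a persistent inward current.  White noise of
    ``noise_sd_pA`` is added to every sample.
    """
    dt = 1.0 / protocol.sample_rate_hz
    n = int(round(protocol.total_s / dt))
    t = np.arange(n) * dt
    volts = np.asarray(protocol.step_voltages_mV, dtype=float)
    rng = np.random.default_rng(seed)
    traces = np.zeros((volts.size, n))

    t_step0 = protocol.pre_s
    t_step1 = protocol.pre_s + protocol.step_s
    in_step = (t >= t_step0) & (t < t_step1)
    in_tail = t >= t_step1
    ts = t[in_step] - t_step0

    for i, v in enumerate(volts):
        a_inf = 1.0 / (1.0 + np.exp((v - v_half_mV) / k_mV))
        if tau_act_s > 0:
            act = a_inf * (1.0 - np.exp(-ts / tau_act_s))
        else:
            act = np.full(ts.shape, a_inf)
        traces[i, in_step] = g_max_nS * act * (v - v_rev_mV)
        if late_plateau_pA != 0.0:
            decay = np.exp(-ts / late_tau_s) if np.isfinite(late_tau_s) else 1.0
            traces[i, in_step] += late_plateau_pA * decay
        if protocol.tail_mV is not None and in_tail.any():
            a_end = act[-1] if act.size else 0.0
            tt = t[in_tail] - t_step1
            traces[i, in_tail] = (
                g_max_nS * a_end * np.exp(-tt / tau_deact_s) * (protocol.tail_mV - v_rev_mV)
            )
    if noise_sd_pA > 0:
        traces = traces + rng.normal(0.0, noise_sd_pA, traces.shape)
    epochs = {"pre": (0.0, t_step0), "step": (t_step0, t_step1)}
    if protocol.tail_mV is not None:
        epochs["tail"] = (t_step1, protocol.total_s)
    return SweepSet(
        time_s=t,
        currents_pA=traces,
        step_voltages_mV=volts,
        epochs=epochs,
        sample_rate_hz=protocol.sample_rate_hz,
    )
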