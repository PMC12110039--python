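"""Synthetic cohort, AOI count-matrix and mIF cell-map generator.

Emulates a 12-patient ovarian HGSC spatial-profiling study: 11 patients
contribute 2 rectangular ROIs and one patient 1 ROI (23 ROIs), each ROI
segmented into three morphology-marker AOIs (PanCK tumor / CD45 immune /
SMA stroma; 69 AOIs).  Counts are negative-binomial around compartment-
specific mixtures of cell-type signature profiles, with group-specific
marker genes planted at stated log2 fold changes and negative probes drawn
from a low-mean background.  Cell maps are marked planar point patterns:
carcinoma cells confined to random disc-shaped tumor nests, immune
phenotypes as homogeneous Poisson processes with compartment-specific
intensities, and — in the recurrence-group defaults — regulatory T cells
placed by a Thomas-type parent-offspring process around cancer cells and
macrophages so that Treg distances to cancer cells are stochastically
smaller than CD8 distances.

Default immune-cell densities are the study-level group means (cells/mm²)
reported for tumor nest and stroma; Treg densities are derived from the
reported Treg/CD8 ratio folds (6.40 in the nest, 2.37 in the stroma) on a
non-recurrence baseline ratio of 0.15.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, box
from shapely.ops import unary_union

from .exceptions import SpatialTMEError
from .panel import CELL_TYPES, builtin_signature, tumor_profile

COMPARTMENTS = ["PanCK", "CD45", "SMA"]
GROUPS = ["non_recur", "recur"]

PHENOTYPES = [
    "cancer",
    "CD8_PD1neg",
    "CD8_PD1pos",
    "Treg",
    "macrophage",
    "NK",
    "other",
]


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(n_patients: int, n_recur: int, seed: int) -> pd.DataFrame:
    """Generate a patient cohort table.

    Recurring patients progress (event=1) with PFS uniform on (3, 60)
    months; non-recurring patients are censored (event=0) with PFS uniform
    on (60, 120) months, i.e. beyond five years.  Deterministic under a
    fixed seed.
    """
    if not 0 <= n_recur <= n_patients:
        raise SpatialTMEError(
            f"n_recur must be in [0, n_patients]; got {n_recur} of {n_patients}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        recur = i < n_recur
        pfs = rng.uniform(3.0, 60.0) if recur else rng.uniform(60.0, 120.0)
        rows.append(
            {
                "patient_id": f"P{i + 1:02d}",
                "group": "recur" if recur else "non_recur",
                "pfs_months": round(float(pfs), 2),
                "event": int(recur),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study design and planted effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """ROI/AOI layout of the profiling run."""

    rois_per_patient: tuple[int, ...]
    roi_width_um: float = 660.0
    roi_height_um: float = 785.0
    compartments: tuple[str, ...] = tuple(COMPARTMENTS)

    @property
    def n_patients(self) -> int:
        return len(self.rois_per_patient)

    @property
    def n_rois(self) -> int:
        return int(sum(self.rois_per_patient))

    @property
    def n_aois(self) -> int:
        return self.n_rois * len(self.compartments)


def default_design(n_patients: int = 12) -> StudyDesign:
    """11 patients x 2 ROIs + 1 patient x 1 ROI, 660 x 785 um, 3 compartments."""
    rois = [2] * (n_patients - 1) + [1]
    return StudyDesign(rois_per_patient=tuple(rois))


@dataclass(frozen=True)
class PlantedEffect:
    """A group-specific expression shift for one gene in one compartment.

    ``log2fc`` is non-recur over recur: positive means higher in the
    non-recurrence group.
    """

    gene: str
    compartment: str
    log2fc: float


def default_planted_effects() -> list[PlantedEffect]:
    """Markers planted at the reported compartment-specific fold changes."""
    return [
        PlantedEffect("TFPI2", "PanCK", 2.0),
        PlantedEffect("PIGR", "PanCK", 2.0),
        PlantedEffect("NKG7", "CD45", 1.32),
        PlantedEffect("CYBB", "CD45", 1.12),
        PlantedEffect("CDH5", "SMA", 1.28),
        PlantedEffect("TRAC", "SMA", 1.23),
        PlantedEffect("EYA2", "PanCK", -1.5),
        PlantedEffect("EYA2", "CD45", -1.5),
    ]


# compartment cell-type mixing weights (cell-fraction scale, renormalized);
# group-dependent entries emulate the reported composition differences
_BASE_MIX: dict[str, dict[str, float]] = {
    "PanCK": {
        "neutrophil": 0.27, "CD4_T": 0.23, "CD8_T": 0.19, "macrophage": 0.08,
        "Treg": 0.04, "NK": 0.04, "B": 0.03, "monocyte": 0.02, "mDC": 0.02,
        "pDC": 0.01, "fibroblast": 0.04, "endothelial": 0.03,
    },
    "CD45": {
        "macrophage": 0.38, "CD8_T": 0.29, "CD4_T": 0.09, "B": 0.05,
        "Treg": 0.05, "NK": 0.04, "monocyte": 0.03, "neutrophil": 0.02,
        "mDC": 0.02, "pDC": 0.01, "fibroblast": 0.01, "endothelial": 0.01,
    },
    "SMA": {
        "fibroblast": 0.27, "CD8_T": 0.27, "CD4_T": 0.13, "macrophage": 0.14,
        "endothelial": 0.06, "Treg": 0.03, "NK": 0.03, "B": 0.02,
        "monocyte": 0.02, "neutrophil": 0.01, "mDC": 0.01, "pDC": 0.01,
    },
}

# (compartment, group) overrides: macrophages enriched in non-recur tissue,
# neutrophils in recur immune segments, monocytes depleted in recur tumor
_GROUP_MIX_OVERRIDE: dict[tuple[str, str], dict[str, float]] = {
    ("CD45", "non_recur"): {"macrophage": 0.46, "neutrophil": 0.007},
    ("CD45", "recur"): {"macrophage": 0.24, "neutrophil": 0.026},
    ("PanCK", "non_recur"): {"monocyte": 0.025, "macrophage": 0.11},
    ("PanCK", "recur"): {"monocyte": 0.001, "macrophage": 0.06},
    ("SMA", "non_recur"): {"macrophage": 0.18},
    ("SMA", "recur"): {"macrophage": 0.10},
}

#: fraction of PanCK segment expression contributed by carcinoma cells
_TUMOR_FRACTION = 0.6


def _mixture_weights(compartment: str, group: str) -> dict[str, float]:
    w = dict(_BASE_MIX[compartment])
    w.update(_GROUP_MIX_OVERRIDE.get((compartment, group), {}))
    total = sum(w.values())
    return {ct: v / total for ct, v in w.items()}


def generate_patient_effects(
    cohort: pd.DataFrame,
    seed: int,
    cell_types: Sequence[str] = ("macrophage",),
    sigma: float = 0.5,
) -> pd.DataFrame:
    """Per-patient lognormal abundance multipliers for selected cell types.

    Applying the same multiplier to the expression mixture and to the cell-map
    densities couples the two platforms, as real tissue does.
    """
    rng = np.random.default_rng(seed)
    mult = {
        ct: np.exp(rng.normal(0.0, sigma, size=len(cohort))) for ct in cell_types
    }
    return pd.DataFrame(mult, index=cohort["patient_id"].to_numpy())


class SyntheticCounts(NamedTuple):
    counts: pd.DataFrame            # genes (incl. negative probes) x AOIs
    is_negative_probe: pd.Series    # per-row flag
    annotation: pd.DataFrame        # one row per AOI


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2."""
    mean = np.clip(mean, 1e-9, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_aoi_counts(
    cohort: pd.DataFrame,
    design: StudyDesign,
    signature: pd.DataFrame | None = None,
    effects: Sequence[PlantedEffect] | None = None,
    n_neg_probes: int = 10,
    seed: int = 0,
    depth: float = 60_000.0,
    dispersion: float = 0.1,
    neg_probe_mean: float = 5.0,
    mixture_concentration: float = 150.0,
    patient_effects: pd.DataFrame | None = None,
) -> SyntheticCounts:
    """Simulate the genes x AOIs count matrix for a cohort and design.

    One AOI per (ROI x compartment).  Expected expression of an AOI is a
    compartment- and group-specific mixture of signature columns (PanCK
    segments additionally carry a carcinoma profile), jittered per AOI by a
    Dirichlet resampling of the mixing weights, multiplied by planted
    per-gene group fold changes, and scaled to ``depth`` total expected
    counts.  Counts are NB(mu, var = mu + dispersion * mu^2); negative
    probes are NB draws around ``neg_probe_mean`` independent of biology.
    """
    if signature is None:
        signature = builtin_signature()
    if effects is None:
        # defaults restricted to the compartments this design actually has
        effects = [
            e for e in default_planted_effects()
            if e.compartment in design.compartments
        ]
    if signature.empty:
        raise SpatialTMEError("signature matrix is empty")
    if n_neg_probes < 2:
        raise SpatialTMEError("need at least 2 negative probes")
    for eff in effects:
        if eff.gene not in signature.index:
            raise SpatialTMEError(f"planted gene {eff.gene!r} absent from the panel")
        if eff.compartment not in design.compartments:
            raise SpatialTMEError(
                f"planted compartment {eff.compartment!r} not in the design"
            )
    if len(cohort) != design.n_patients:
        raise SpatialTMEError(
            f"cohort has {len(cohort)} patients but design expects {design.n_patients}"
        )

    rng = np.random.default_rng(seed)
    genes = signature.index.to_numpy()
    # column-normalized profiles: expression share of each cell type
    profiles = signature / signature.sum(axis=0)
    tumor = tumor_profile().reindex(signature.index).fillna(0.0)
    tumor = tumor / tumor.sum()

    # planted fold changes, applied symmetrically around the shared mean
    fc = {
        (c, g): np.ones(len(genes))
        for c in design.compartments
        for g in GROUPS
    }
    gene_pos = {g: i for i, g in enumerate(genes)}
    for eff in effects:
        i = gene_pos[eff.gene]
        fc[(eff.compartment, "non_recur")][i] *= 2.0 ** (eff.log2fc / 2.0)
        fc[(eff.compartment, "recur")][i] *= 2.0 ** (-eff.log2fc / 2.0)

    aoi_ids, columns, annot_rows = [], [], []
    for patient, n_rois in zip(cohort.itertuples(index=False), design.rois_per_patient):
        for roi in range(1, n_rois + 1):
            roi_id = f"{patient.patient_id}_R{roi}"
            for comp in design.compartments:
                weights = _mixture_weights(comp, patient.group)
                if patient_effects is not None:
                    for ct in patient_effects.columns:
                        if ct in weights:
                            weights[ct] *= float(
                                patient_effects.loc[patient.patient_id, ct]
                            )
                w = np.array([weights.get(ct, 0.0) for ct in profiles.columns])
                w = w / w.sum()
                w = rng.dirichlet(w * mixture_concentration)
                mu = profiles.to_numpy() @ w
                if comp == "PanCK":
                    mu = (1 - _TUMOR_FRACTION) * mu + _TUMOR_FRACTION * tumor.to_numpy()
                mu = mu * fc[(comp, patient.group)]
                mu = depth * mu / mu.sum()
                counts = _nb_draw(rng, mu, dispersion)
                aoi_id = f"{roi_id}_{comp}"
                aoi_ids.append(aoi_id)
                columns.append(counts)
                annot_rows.append(
                    {
                        "aoi_id": aoi_id,
                        "patient_id": patient.patient_id,
                        "roi_id": roi_id,
                        "compartment": comp,
                        "group": patient.group,
                    }
                )

    bio = pd.DataFrame(
        np.column_stack(columns), index=genes, columns=aoi_ids
    )
    neg_names = [f"NegProbe-{i + 1:02d}" for i in range(n_neg_probes)]
    neg = pd.DataFrame(
        _nb_draw(
            rng,
            np.full((n_neg_probes, len(aoi_ids)), neg_probe_mean),
            dispersion,
        ),
        index=neg_names,
        columns=aoi_ids,
    )
    counts = pd.concat([bio, neg])
    flags = pd.Series(
        [False] * len(genes) + [True] * n_neg_probes, index=counts.index
    )
    return SyntheticCounts(counts, flags, pd.DataFrame(annot_rows))


# ---------------------------------------------------------------------------
# mIF cell maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellMapParams:
    """Point-process settings for one simulated tissue window.

    Densities are cells/mm² as (tumor_nest, stroma) pairs.  With
    ``treg_clustered`` the Tregs of each compartment are offspring of
    randomly chosen parents (cancer cells or macrophages of the same
    compartment), displaced by an isotropic Gaussian of ``treg_parent_sd_um``.
    """

    window_w_um: float = 660.0
    window_h_um: float = 785.0
    n_nests: int = 4
    nest_radius_um: float = 130.0
    cancer_density_nest: float = 800.0
    densities: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "CD8_PD1neg": (231.2, 256.6),
            "CD8_PD1pos": (57.8, 64.1),
            "Treg": (43.4, 48.1),
            "macrophage": (270.3, 443.2),
            "NK": (40.0, 60.0),
        }
    )
    treg_clustered: bool = False
    treg_parent_sd_um: float = 8.0
    treg_cancer_parent_frac: float = 0.6


def default_cell_map_params(group: str) -> CellMapParams:
    """Group defaults: reported density means; recur maps get the low-density,
    high-Treg-ratio, Treg-clustered configuration."""
    if group == "non_recur":
        return CellMapParams()
    if group == "recur":
        return CellMapParams(
            densities={
                "CD8_PD1neg": (37.3, 88.0),
                "CD8_PD1pos": (9.3, 22.0),
                "Treg": (44.7, 39.1),
                "macrophage": (137.2, 332.5),
                "NK": (20.0, 30.0),
            },
            treg_clustered=True,
        )
    raise SpatialTMEError(f"unknown group {group!r}")


@dataclass
class CellMap:
    """A marked planar point pattern with its window and nest geometry."""

    cells: pd.DataFrame             # cell_id, x_um, y_um, phenotype, compartment
    window_w_um: float
    window_h_um: float
    nests: list[tuple[float, float, float]]   # (cx, cy, r) discs, um

    @property
    def nest_area_mm2(self) -> float:
        return _nest_union_area_um2(self.nests, self.window_w_um, self.window_h_um) / 1e6

    @property
    def stroma_area_mm2(self) -> float:
        total = self.window_w_um * self.window_h_um / 1e6
        return total - self.nest_area_mm2

    def compartment_area_mm2(self, compartment: str) -> float:
        if compartment == "tumor_nest":
            return self.nest_area_mm2
        if compartment == "stroma":
            return self.stroma_area_mm2
        if compartment == "all":
            return self.window_w_um * self.window_h_um / 1e6
        raise SpatialTMEError(f"unknown compartment {compartment!r}")


def _nest_union_area_um2(nests, w, h) -> float:
    if not nests:
        return 0.0
    discs = unary_union([Point(cx, cy).buffer(r, quad_segs=128) for cx, cy, r in nests])
    return float(discs.intersection(box(0, 0, w, h)).area)


def in_any_nest(x, y, nests) -> np.ndarray:
    """Boolean mask: point inside (or on the boundary of) any nest disc."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    inside = np.zeros(x.shape, dtype=bool)
    for cx, cy, r in nests:
        inside |= (x - cx) ** 2 + (y - cy) ** 2 <= r**2
    return inside


def _sample_in_compartment(rng, n, nests, w, h, compartment, max_batches=2000):
    """Uniform points within the nest union or its complement, by rejection."""
    xs, ys = [], []
    got = 0
    batches = 0
    while got < n:
        m = max(4 * (n - got), 32)
        x = rng.uniform(0, w, m)
        y = rng.uniform(0, h, m)
        mask = in_any_nest(x, y, nests)
        if compartment == "stroma":
            mask = ~mask
        xs.append(x[mask])
        ys.append(y[mask])
        got += int(mask.sum())
        batches += 1
        if batches > max_batches:
            raise SpatialTMEError(
                f"cannot place points in {compartment}: region too small"
            )
    x = np.concatenate(xs)[:n]
    y = np.concatenate(ys)[:n]
    return x, y


def generate_cell_map(
    group: str,
    params: CellMapParams | None = None,
    seed: int = 0,
) -> CellMap:
    """Simulate one mIF tissue window for a patient of the given group."""
    if params is None:
        params = default_cell_map_params(group)
    for pheno, (dn, ds) in params.densities.items():
        if dn < 0 or ds < 0:
            raise SpatialTMEError(f"negative intensity for {pheno!r}")
    if params.cancer_density_nest < 0:
        raise SpatialTMEError("negative cancer intensity")
    if params.window_w_um <= 0 or params.window_h_um <= 0:
        raise SpatialTMEError("window dimensions must be positive")

    rng = np.random.default_rng(seed)
    w, h, r = params.window_w_um, params.window_h_um, params.nest_radius_um
    if params.n_nests > 0 and (w < 2 * r or h < 2 * r):
        raise SpatialTMEError("window too small for the nest radius")
    nests = [
        (float(rng.uniform(r, w - r)), float(rng.uniform(r, h - r)), r)
        for _ in range(params.n_nests)
    ]
    nest_area = _nest_union_area_um2(nests, w, h) / 1e6
    stroma_area = w * h / 1e6 - nest_area

    records: list[dict] = []

    def _add(x, y, phenotype):
        inside = in_any_nest(x, y, nests)
        for xi, yi, ins in zip(x, y, inside):
            records.append(
                {
                    "x_um": float(xi),
                    "y_um": float(yi),
                    "phenotype": phenotype,
                    "compartment": "tumor_nest" if ins else "stroma",
                }
            )

    # carcinoma cells inside nests
    if params.n_nests > 0 and nest_area > 0:
        n_cancer = rng.poisson(params.cancer_density_nest * nest_area)
        if n_cancer:
            x, y = _sample_in_compartment(rng, n_cancer, nests, w, h, "tumor_nest")
            _add(x, y, "cancer")

    deferred_treg: list[tuple[str, int]] = []
    for pheno in sorted(params.densities):
        dn, ds = params.densities[pheno]
        for comp, dens, area in (
            ("tumor_nest", dn, nest_area),
            ("stroma", ds, stroma_area),
        ):
            if area <= 0 or dens == 0:
                continue
            n = int(rng.poisson(dens * area))
            if n == 0:
                continue
            if pheno == "Treg" and params.treg_clustered:
                deferred_treg.append((comp, n))
                continue
            x, y = _sample_in_compartment(rng, n, nests, w, h, comp)
            _add(x, y, pheno)

    # Thomas-type Treg placement: parents are cancer cells or macrophages
    # whose Gaussian offspring can land in the Treg's compartment.  For
    # stroma Tregs the eligible cancer parents are those near a nest
    # boundary (within 3 sd of it); macrophage parents share the compartment.
    for comp, n in deferred_treg:
        placed = pd.DataFrame(records)
        mac_parents = placed[
            (placed["compartment"] == comp) & (placed["phenotype"] == "macrophage")
        ]
        cancer_all = placed[placed["phenotype"] == "cancer"]
        if comp == "tumor_nest" or cancer_all.empty:
            cancer_parents = cancer_all
        else:
            depth = np.full(len(cancer_all), np.inf)
            cx = cancer_all["x_um"].to_numpy()
            cy = cancer_all["y_um"].to_numpy()
            for ncx, ncy, nr in nests:
                d = nr - np.hypot(cx - ncx, cy - ncy)
                depth = np.minimum(depth, np.where(d >= 0, d, np.inf))
            cancer_parents = cancer_all[depth <= 1.5 * params.treg_parent_sd_um]
        parents = pd.concat([cancer_parents, mac_parents])
        if parents.empty:
            x, y = _sample_in_compartment(rng, n, nests, w, h, comp)
            _add(x, y, "Treg")
            continue
        xs, ys = [], []
        for _ in range(n):
            use_cancer = (
                len(cancer_parents) > 0
                and (len(mac_parents) == 0
                     or rng.uniform() < params.treg_cancer_parent_frac)
            )
            pool = cancer_parents if use_cancer else mac_parents
            row = pool.iloc[rng.integers(len(pool))]
            for _try in range(200):
                xi = row["x_um"] + rng.normal(0, params.treg_parent_sd_um)
                yi = row["y_um"] + rng.normal(0, params.treg_parent_sd_um)
                in_window = 0 <= xi <= w and 0 <= yi <= h
                if in_window:
                    ins = bool(in_any_nest(xi, yi, nests)[0])
                    if ("tumor_nest" if ins else "stroma") == comp:
                        break
            else:
                # compartment must be preserved: fall back to a uniform draw
                xf, yf = _sample_in_compartment(rng, 1, nests, w, h, comp)
                xi, yi = float(xf[0]), float(yf[0])
            xs.append(xi)
            ys.append(yi)
        _add(np.array(xs), np.array(ys), "Treg")

    cells = pd.DataFrame(records, columns=["x_um", "y_um", "phenotype", "compartment"])
    cells.insert(0, "cell_id", [f"c{i + 1:05d}" for i in range(len(cells))])
    return CellMap(cells=cells, window_w_um=w, window_h_um=h, nests=nests)


_MARKERS = ["CK", "CD8", "PD1", "CD68", "FOXP3", "CD56"]
_PHENOTYPE_MARKERS = {
    "cancer": ["CK"],
    "CD8_PD1neg": ["CD8"],
    "CD8_PD1pos": ["CD8", "PD1"],
    "Treg": ["FOXP3"],
    "macrophage": ["CD68"],
    "NK": ["CD56"],
    "other": [],
}


def attach_marker_intensities(
    cells: pd.DataFrame,
    seed: int = 0,
    positive_mean: float = 10.0,
    negative_mean: float = 1.0,
    sd: float = 1.0,
) -> pd.DataFrame:
    """Add per-marker fluorescence intensities consistent with phenotypes.

    Positive markers draw from N(positive_mean, sd), negatives from
    N(negative_mean, sd) truncated at 0 — two well-separated modes so that
    threshold gating can be validated against the known labels.
    """
    rng = np.random.default_rng(seed)
    out = cells.copy()
    for marker in _MARKERS:
        pos = out["phenotype"].map(
            lambda p: marker in _PHENOTYPE_MARKERS.get(p, [])
        ).to_numpy()
        mu = np.where(pos, positive_mean, negative_mean)
        out[marker] = np.clip(rng.normal(mu, sd), 0.0, None)
    return out


def cohort_cell_maps(
    cohort: pd.DataFrame,
    seed: int = 0,
    params_by_group: Mapping[str, CellMapParams] | None = None,
    density_scale: pd.DataFrame | None = None,
) -> dict[str, CellMap]:
    """One cell map per patient; optional per-patient density multipliers.

    ``density_scale`` (patients x phenotypes, e.g. from
    :func:`generate_patient_effects` with cell-type names mapped to
    phenotypes) scales that patient's densities, coupling mIF abundance to
    the expression generator.
    """
    maps: dict[str, CellMap] = {}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(cohort)) % (2**31)
    for (_, row), s in zip(cohort.iterrows(), child_seeds):
        params = (
            params_by_group[row["group"]]
            if params_by_group is not None
            else default_cell_map_params(row["group"])
        )
        if density_scale is not None and row["patient_id"] in density_scale.index:
            dens = dict(params.densities)
            for pheno in density_scale.columns:
                if pheno in dens:
                    m = float(density_scale.loc[row["patient_id"], pheno])
                    dens[pheno] = (dens[pheno][0] * m, dens[pheno][1] * m)
            params = replace(params, densities=dens)
        maps[row["patient_id"]] = generate_cell_map(row["group"], params, seed=int(s))
    return maps
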