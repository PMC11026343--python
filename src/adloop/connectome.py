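"""Structural connectomes: I/O, validation, annotation, and graph operators.

A connectome couples the two halves of the model: its weights enter the
brain-network model as coupling strengths and (divided by tract length) the
protein-propagation model as a diffusion operator; its tract lengths set the
axonal conduction delays.  Weights are max-normalized to [0, 1] once, at load
or synthesis, so that the global coupling factor ``g`` and the diffusion
constant ``rho`` are scale-free across connectomes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RegionInfo",
    "Connectome",
    "load_connectome",
    "synthetic_connectome",
    "normalize_weights",
    "graph_laplacian",
    "diffusion_laplacian",
    "cingulum_regions",
    "validate_connectome",
]

#: The eight anatomical categories used by the bundled annotation.
GROUPS = (
    "frontal",
    "anterior-cingulate",
    "posterior-cingulate",
    "parietal",
    "temporal",
    "insula",
    "medial-temporal",
    "subcortical",
)

BRAAK_STAGES = ("I", "II", "III", "IV", "V", "none")

#: Antero-posterior classification by anatomical group.  Anterior = frontal
#: lobe plus anterior cingulate; posterior = parietal lobe plus posterior
#: cingulate (incl. precuneus and isthmus); everything else is excluded from
#: the antero-posterior contrasts.
AP_FROM_GROUP = {
    "frontal": "anterior",
    "anterior-cingulate": "anterior",
    "posterior-cingulate": "posterior",
    "parietal": "posterior",
    "temporal": "excluded",
    "insula": "excluded",
    "medial-temporal": "excluded",
    "subcortical": "excluded",
}

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class RegionInfo:
    """Per-region annotation: anatomy, Braak stage and seeding flags."""

    name: str
    hemisphere: str  # "left" | "right"
    group: str  # one of GROUPS
    ap_class: str  # "anterior" | "posterior" | "excluded"
    braak_stage: str  # "I".."V" or "none"
    abeta_seed: bool = False
    tau_seed: bool = False

    def __post_init__(self):
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"bad hemisphere {self.hemisphere!r}")
        if self.group not in GROUPS:
            raise ValueError(f"bad group {self.group!r}")
        if self.ap_class not in ("anterior", "posterior", "excluded"):
            raise ValueError(f"bad ap_class {self.ap_class!r}")
        if self.braak_stage not in BRAAK_STAGES:
            raise ValueError(f"bad braak_stage {self.braak_stage!r}")


@dataclass
class Connectome:
    """A structural connectome.

    Attributes
    ----------
    weights : (n, n) ndarray
        Symmetric, non-negative connection weights (streamline counts,
        max-normalized to [0, 1]); zero diagonal.
    lengths : (n, n) ndarray
        Symmetric tract lengths in mm; positive wherever ``weights`` is.
    regions : list of RegionInfo
        Row-order-matched annotations.
    """

    weights: np.ndarray
    lengths: np.ndarray
    regions: list[RegionInfo] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def stage_map(self) -> list[str]:
        """Braak-stage label per region (``'I'..'V'`` or ``'none'``)."""
        return [r.braak_stage for r in self.regions]

    def indices(self, **criteria) -> np.ndarray:
        """Indices of regions whose RegionInfo fields match ``criteria``."""
        out = []
        for i, r in enumerate(self.regions):
            if all(getattr(r, k) == v for k, v in criteria.items()):
                out.append(i)
        return np.asarray(out, dtype=int)

    def homolog_pairs(self) -> list[tuple[int, int]]:
        """(left, right) index pairs matched by region name without the
        leading hemisphere word."""
        def stem(name: str) -> str:
            first, _, rest = name.partition(" ")
            return rest if first.lower() in ("left", "right") else name

        left = {stem(r.name): i for i, r in enumerate(self.regions)
                if r.hemisphere == "left"}
        pairs = []
        for i, r in enumerate(self.regions):
            if r.hemisphere == "right":
                s = stem(r.name)
                if s in left:
                    pairs.append((left[s], i))
        return pairs

    def to_files(self, directory: str | Path) -> None:
        """Write weights/lengths as whitespace-delimited text plus an
        annotation CSV (``weights.txt``, ``lengths.txt``, ``regions.csv``)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "weights.txt", self.weights)
        np.savetxt(directory / "lengths.txt", self.lengths)
        pd.DataFrame(
            [
                dict(
                    name=r.name,
                    hemisphere=r.hemisphere,
                    group=r.group,
                    ap_class=r.ap_class,
                    braak_stage=r.braak_stage,
                    abeta_seed=int(r.abeta_seed),
                    tau_seed=int(r.tau_seed),
                )
                for r in self.regions
            ]
        ).to_csv(directory / "regions.csv", index=False)


def _read_matrix(path: str | Path) -> np.ndarray:
    """Read a whitespace- or comma-delimited numeric matrix, no header."""
    text = Path(path).read_text()
    if "," in text:
        text = text.replace(",", " ")
    try:
        mat = np.loadtxt(io.StringIO(text), ndmin=2)
    except ValueError as exc:
        raise ValueError(f"could not parse matrix file {path}: {exc}") from exc
    return mat


def _read_annotations(path: str | Path) -> list[RegionInfo]:
    df = pd.read_csv(path)
    required = {"name", "hemisphere", "group", "ap_class", "braak_stage",
                "abeta_seed", "tau_seed"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    return [
        RegionInfo(
            name=str(row["name"]),
            hemisphere=str(row["hemisphere"]),
            group=str(row["group"]),
            ap_class=str(row["ap_class"]),
            braak_stage=str(row["braak_stage"]),
            abeta_seed=bool(int(row["abeta_seed"])),
            tau_seed=bool(int(row["tau_seed"])),
        )
        for _, row in df.iterrows()
    ]


def validate_connectome(con: Connectome) -> Connectome:
    """Check the structural invariants; raise ``ValueError`` on violation."""
    w, ell = np.asarray(con.weights, float), np.asarray(con.lengths, float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"weights must be square, got {w.shape}")
    if ell.shape != w.shape:
        raise ValueError(
            f"dimension mismatch: weights {w.shape} vs lengths {ell.shape}")
    if con.regions and len(con.regions) != w.shape[0]:
        raise ValueError(
            f"{len(con.regions)} annotation rows for {w.shape[0]} regions")
    if np.any(w < 0):
        raise ValueError("negative weights")
    if np.any(ell < 0):
        raise ValueError("negative lengths")
    for name, m in (("weights", w), ("lengths", ell)):
        if not np.allclose(m, m.T, atol=_SYMMETRY_TOL, rtol=0):
            raise ValueError(f"{name} asymmetric beyond tolerance "
                             f"{_SYMMETRY_TOL}")
    if np.any(np.abs(np.diag(w)) > _SYMMETRY_TOL):
        raise ValueError("weights diagonal must be zero")
    off = w > 0
    np.fill_diagonal(off, False)
    if np.any(off & (ell <= 0)):
        raise ValueError("zero tract length on a connected pair")
    return con


def load_connectome(
    weights_path: str | Path,
    lengths_path: str | Path,
    annotations_path: str | Path | None = None,
) -> Connectome:
    """Read and validate a connectome from delimited-text files.

    Weights are max-normalized after validation.  Inputs asymmetric within
    1e-9 are symmetrized by averaging; larger asymmetry is an error.
    """
    w = _read_matrix(weights_path)
    ell = _read_matrix(lengths_path)
    regions = _read_annotations(annotations_path) if annotations_path else []
    con = Connectome(weights=w, lengths=ell, regions=regions)
    validate_connectome(con)
    con.weights = normalize_weights(0.5 * (w + w.T))
    con.lengths = 0.5 * (ell + ell.T)
    np.fill_diagonal(con.weights, 0.0)
    return con


def normalize_weights(weights: np.ndarray) -> np.ndarray:
    """Rescale a non-negative matrix so its maximum entry equals 1.

    The zero matrix is returned unchanged; entry ratios are preserved.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative entries")
    m = w.max(initial=0.0)
    return w.copy() if m == 0 else w / m


def graph_laplacian(weights: np.ndarray) -> np.ndarray:
    """Graph Laplacian ``L_ij = -w_ij + delta_ij * sum_j w_ij``.

    Rows sum to zero by construction, so diffusion under ``-L`` conserves
    total concentration.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"non-square input {w.shape}")
    return np.diag(w.sum(axis=1)) - w


def diffusion_laplacian(weights: np.ndarray, lengths_mm: np.ndarray) -> np.ndarray:
    """Laplacian of the length-scaled adjacency ``a_ij = w_ij / L_ij``.

    Tract lengths are converted to cm so that the diffusion constant rho
    (cm/yr) times this operator has units of 1/yr.  Unconnected pairs
    contribute nothing regardless of their length entry.
    """
    w = np.asarray(weights, float)
    ell_cm = np.asarray(lengths_mm, float) / 10.0
    a = np.zeros_like(w)
    mask = w > 0
    np.fill_diagonal(mask, False)
    a[mask] = w[mask] / ell_cm[mask]
    return graph_laplacian(a)


def cingulum_regions() -> list[RegionInfo]:
    """The bundled 40-region cingulum-bundle annotation.

    Regions 0..19 are the left hemisphere, 20..39 the right, in matched
    order.  Seeding flags: toxic tau seeds at the entorhinal pair; toxic
    amyloid-beta seeds at lateral/medial orbitofrontal, insula, posterior and
    isthmus cingulate, and precuneus (six bilateral pairs).  Braak stages:
    I entorhinal; II hippocampus; III parahippocampal + amygdala; IV insula,
    posterior cingulate, inferior temporal, inferior parietal (both
    hemispheres); V remaining cortex; thalamus unstaged.
    """
    ref = resources.files("adloop.data") / "cingulum40.csv"
    with resources.as_file(ref) as path:
        return _read_annotations(path)


def _generic_regions(n_pairs: int) -> list[RegionInfo]:
    """Annotation schema for a synthetic bilateral network of arbitrary size.

    Mirrors the bundled schema: pair 0 is the entorhinal homolog (tau seed,
    stage I), pairs 1-4 carry stages II-V through the medial-temporal /
    insula / temporal groups, later pairs are stage-V cortex alternating
    between anterior (frontal, anterior cingulate) and posterior (parietal,
    posterior cingulate) groups.  Six amyloid seed pairs are spread over the
    insula and stage-V cortex.
    """
    if n_pairs < 5:
        raise ValueError(
            f"n_pairs={n_pairs} too small to host all five Braak stage groups")
    base = [
        ("entorhinal homolog", "medial-temporal", "I"),
        ("hippocampus homolog", "medial-temporal", "II"),
        ("parahippocampal homolog", "medial-temporal", "III"),
        ("insula homolog", "insula", "IV"),
        ("inferior temporal homolog", "temporal", "V"),
    ]
    cortical_cycle = ("frontal", "anterior-cingulate", "parietal",
                      "posterior-cingulate")
    specs: list[tuple[str, str, str]] = list(base)
    for k in range(5, n_pairs):
        grp = cortical_cycle[(k - 5) % len(cortical_cycle)]
        specs.append((f"{grp} area {(k - 5) // len(cortical_cycle) + 1}",
                      grp, "V"))

    ab_candidates = [3] + list(range(4, n_pairs))
    n_ab = min(6, len(ab_candidates))
    sel = np.unique(np.round(
        np.linspace(0, len(ab_candidates) - 1, n_ab)).astype(int))
    ab_pairs = {ab_candidates[i] for i in sel}

    def mk(hemi: str) -> list[RegionInfo]:
        out = []
        for k, (stem, grp, stage) in enumerate(specs):
            out.append(RegionInfo(
                name=f"{hemi.capitalize()} {stem}",
                hemisphere=hemi,
                group=grp,
                ap_class=AP_FROM_GROUP[grp],
                braak_stage=stage,
                abeta_seed=k in ab_pairs,
                tau_seed=k == 0,
            ))
        return out

    return mk("left") + mk("right")


def _stage_rank(stage: str) -> int:
    return BRAAK_STAGES.index(stage)


def synthetic_connectome(
    n_pairs: int,
    topology: str = "modular",
    rng_seed: int = 0,
) -> Connectome:
    """Generate a bilateral synthetic connectome of ``2 * n_pairs`` regions.

    Parameters
    ----------
    n_pairs : int
        Homologous region pairs per hemisphere (>= 5, so that all five Braak
        stage groups are represented).  ``n_pairs=20`` reuses the bundled
        cingulum-bundle annotation verbatim.
    topology : {"modular", "distance", "path"}
        ``modular``: two densely connected hemispheric modules with
        heavy-tailed (lognormal) weights and sparse homotopic bridges —
        the default stand-in for an empirical tractography network.
        ``distance``: regions embedded in 3-D mirrored coordinates, weights
        decaying exponentially with Euclidean distance.
        ``path``: a Hamiltonian path per hemisphere visiting regions in
        Braak-stage order plus one interhemispheric link between the
        stage-I homologs; used for wavefront-propagation checks.
    rng_seed : int
        Weights and lengths are deterministic given the seed.

    Both hemispheric blocks are exact mirrors, so bilateral seeding evolves
    hemisphere-symmetrically.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    regions = (cingulum_regions() if n_pairs == 20
               else _generic_regions(n_pairs))
    rng = np.random.default_rng(rng_seed)
    m = n_pairs
    n = 2 * m
    w = np.zeros((n, n))
    ell = np.zeros((n, n))

    def set_edge(i, j, wij, lij):
        w[i, j] = w[j, i] = wij
        ell[i, j] = ell[j, i] = lij

    if topology == "path":
        order = sorted(range(m), key=lambda k: (_stage_rank(
            regions[k].braak_stage), k))
        # heterogeneous (lognormal) weights, mirrored across hemispheres
        path_w = rng.lognormal(mean=0.0, sigma=1.2, size=m - 1)
        path_l = rng.uniform(15, 150, size=m - 1)
        for hemi in (0, m):
            for (a, b), wij, lij in zip(zip(order[:-1], order[1:]),
                                        path_w, path_l):
                set_edge(hemi + a, hemi + b, wij, lij)
        # one interhemispheric link between the stage-I path heads
        head = order[0]
        set_edge(head, m + head, rng.lognormal(0.0, 0.6),
                 rng.uniform(60, 150))
    elif topology == "distance":
        lam = 40.0  # mm, decay scale of weight with distance
        pos = rng.uniform(0, 100, size=(m, 3))
        pos_l = pos + np.array([-60.0, 0, 0])
        pos_r = pos * np.array([-1.0, 1, 1]) + np.array([60.0, 0, 0])
        coords = np.vstack([pos_l, pos_r])
        for i in range(n):
            for j in range(i + 1, n):
                same_hemi = (i < m) == (j < m)
                homotopic = abs(i - j) == m
                if not (same_hemi or homotopic):
                    continue
                d = float(np.linalg.norm(coords[i] - coords[j]))
                wij = np.exp(-d / lam)
                if wij < 0.05:
                    continue
                set_edge(i, j, wij, np.clip(d, 15.0, 150.0))
    elif topology == "modular":
        # heavy-tailed intra-hemispheric weights at ~25% density, mirrored,
        # plus homotopic bridges on ~1/3 of the pairs
        dens = 0.25
        for a in range(m):
            for b in range(a + 1, m):
                if rng.random() < dens:
                    wij = rng.lognormal(mean=0.0, sigma=1.2)
                    lij = rng.uniform(15, 150)
                    set_edge(a, b, wij, lij)
                    set_edge(m + a, m + b, wij, lij)
        # spanning path guarantees intra-hemisphere connectivity
        perm = rng.permutation(m)
        for a, b in zip(perm[:-1], perm[1:]):
            if w[a, b] == 0:
                wij = rng.lognormal(mean=0.0, sigma=1.2)
                lij = rng.uniform(15, 150)
                set_edge(a, b, wij, lij)
                set_edge(m + a, m + b, wij, lij)
        k_bridge = max(1, m // 3)
        bridge = rng.choice(m, size=k_bridge, replace=False)
        for a in bridge:
            set_edge(a, m + a, rng.lognormal(mean=0.0, sigma=0.6),
                     rng.uniform(60, 150))
        # One dominant homotopic tract (the subcortical pair where the
        # annotation has one) anchors the max-normalization so that, at the
        # default global coupling, every cortical region's total incoming
        # drive stays small enough to keep its mass on the alpha branch --
        # the baseline operating point the coupled model requires.
        sub = [k for k in range(m) if regions[k].group == "subcortical"]
        anchor = sub[0] if sub else min(1, m - 1)
        w_anchor = 8.0 * w.sum(axis=1).max()
        set_edge(anchor, m + anchor, w_anchor, rng.uniform(60, 150))
    else:
        raise ValueError(f"unknown topology {topology!r}")

    con = Connectome(weights=normalize_weights(w), lengths=ell,
                     regions=regions)
    return validate_connectome(con)
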