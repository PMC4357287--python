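"""Geometric morphometrics of 2-D landmark configurations.

The mouth (stoma) of each specimen is captured by 11 fixed landmarks in
lateral view.  The workflow is the standard one: generalized Procrustes
analysis (GPA) removes position, orientation and scale; species (or morph)
means are taken on within-unit aligned coordinates; Procrustes shape
coordinates optionally augmented with log centroid size give "form space";
principal component analysis — ordinary or phylogenetically corrected —
summarizes the resulting morphospace.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import Phylogeny

N_LANDMARKS = 11


class TPSError(ValueError):
    pass


@dataclass
class LandmarkConfig:
    """One specimen's landmark configuration.

    ``cs`` may be set explicitly (e.g., a mean raw centroid size carried
    alongside unit-scaled mean coordinates); otherwise centroid size is
    computed from ``coords``.
    """

    specimen_id: str
    coords: np.ndarray
    species: str | None = None
    morph: str | None = None  # "St" | "Eu" | "monomorphic" | None
    cs: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (k, 2)")

    @property
    def centroid_size(self) -> float:
        return self.cs if self.cs is not None else centroid_size(self.coords)

    @property
    def unit(self) -> str:
        """Label of the averaging unit: species, suffixed by morph if dimorphic."""
        sp = self.species if self.species is not None else self.specimen_id
        if self.morph in ("St", "Eu"):
            return f"{sp}_{self.morph}"
        return sp


def centroid_size(coords: np.ndarray) -> float:
    """Square root of the summed squared landmark distances to their centroid."""
    coords = np.asarray(coords, dtype=float)
    cs = float(np.sqrt(((coords - coords.mean(axis=0)) ** 2).sum()))
    if cs == 0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return cs


# --------------------------------------------------------------------------
# TPS I/O
# --------------------------------------------------------------------------

def read_tps(source, n_landmarks: int = N_LANDMARKS) -> list[LandmarkConfig]:
    """Read a TPS file (as written by tpsDig-style digitizers).

    Records start with ``LM=k`` followed by k coordinate pairs and optional
    ``IMAGE=``, ``ID=`` and ``SCALE=`` keys; SCALE is applied
    multiplicatively.  IDs of the form ``species__morph__n`` (double
    underscores) are unpacked into species and morph fields.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = str(source)
    configs: list[LandmarkConfig] = []
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    i = 0
    rec = 0
    while i < len(lines):
        m = re.match(r"LM\s*=\s*(\d+)$", lines[i], flags=re.I)
        if not m:
            raise TPSError(f"expected LM= at line {i + 1}, got {lines[i]!r}")
        rec += 1
        k = int(m.group(1))
        if k != n_landmarks:
            raise TPSError(f"record {rec}: LM={k}, expected {n_landmarks}")
        i += 1
        pts = []
        while i < len(lines) and re.match(r"[-+0-9.]", lines[i]):
            vals = lines[i].split()
            if len(vals) != 2:
                raise TPSError(f"record {rec}: expected coordinate pair, "
                               f"got {lines[i]!r}")
            pts.append([float(vals[0]), float(vals[1])])
            i += 1
        if len(pts) != k:
            raise TPSError(f"record {rec}: {len(pts)} points for LM={k}")
        keys: dict[str, str] = {}
        while i < len(lines) and "=" in lines[i] and not lines[i].upper().startswith("LM"):
            key, _, val = lines[i].partition("=")
            keys[key.strip().upper()] = val.strip()
            i += 1
        coords = np.asarray(pts)
        if "SCALE" in keys:
            coords = coords * float(keys["SCALE"])
        spec_id = keys.get("ID") or keys.get("IMAGE") or f"record{rec}"
        species = morph = None
        if "__" in spec_id:
            parts = spec_id.split("__")
            if len(parts) >= 2:
                species = parts[0]
                morph = parts[1] if parts[1] in ("St", "Eu", "monomorphic") else None
        configs.append(LandmarkConfig(specimen_id=spec_id, coords=coords,
                                      species=species, morph=morph))
    if not configs:
        raise TPSError("no TPS records found")
    return configs


def write_tps(configs: list[LandmarkConfig], path) -> None:
    with open(path, "w") as fh:
        for c in configs:
            fh.write(f"LM={c.coords.shape[0]}\n")
            for x, y in c.coords:
                fh.write(f"{x:.10g} {y:.10g}\n")
            fh.write(f"ID={c.specimen_id}\n")


# --------------------------------------------------------------------------
# Generalized Procrustes analysis
# --------------------------------------------------------------------------

@dataclass
class ShapeCoords:
    """Procrustes-aligned configurations plus their consensus."""

    aligned: np.ndarray        # (n, k, 2), centered, unit centroid size
    consensus: np.ndarray      # (k, 2)
    labels: list[str]
    iterations: int = 0

    def flat(self) -> pd.DataFrame:
        """(n, 2k) DataFrame of shape coordinates (x1, y1, x2, y2, ...)."""
        n, k, _ = self.aligned.shape
        cols = [f"{ax}{j + 1}" for j in range(k) for ax in ("x", "y")]
        return pd.DataFrame(self.aligned.reshape(n, 2 * k), index=self.labels,
                            columns=cols)


def _optimal_rotation(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Rotation R minimizing ||X R - Y||, reflections forbidden."""
    H = X.T @ Y
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, d]) @ Vt


def _normalize(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    return c / centroid_size(c)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations."""
    a, b = _normalize(a), _normalize(b)
    return float(np.linalg.norm(a @ _optimal_rotation(a, b) - b))


def gpa(configs, tol: float = 1e-10, max_iter: int = 100) -> ShapeCoords:
    """Generalized Procrustes analysis.

    Each configuration is centered and scaled to unit centroid size, then
    iteratively rotated (no reflections) to the running consensus, which is
    re-estimated as the arithmetic mean and renormalized, until the
    consensus RMS change falls below ``tol``.
    """
    if isinstance(configs, np.ndarray):
        arrays = [configs[i] for i in range(configs.shape[0])]
        labels = [f"config{i + 1}" for i in range(len(arrays))]
    else:
        arrays = [c.coords for c in configs]
        labels = [getattr(c, "specimen_id", f"config{i + 1}")
                  for i, c in enumerate(configs)]
    if len(arrays) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    ks = {a.shape for a in arrays}
    if len(ks) != 1:
        raise ValueError(f"inconsistent landmark counts: {ks}")
    X = np.stack([_normalize(a) for a in arrays])
    consensus = X[0].copy()
    for it in range(1, max_iter + 1):
        for i in range(len(X)):
            X[i] = X[i] @ _optimal_rotation(X[i], consensus)
        new = _normalize(X.mean(axis=0))
        change = np.sqrt(((new - consensus) ** 2).mean())
        consensus = new
        if change < tol:
            return ShapeCoords(aligned=X, consensus=consensus, labels=labels,
                               iterations=it)
    raise RuntimeError(
        f"GPA did not converge in {max_iter} iterations (last RMS change "
        f"{change:.3e}, tol {tol:.0e})")


def species_average(configs: list[LandmarkConfig]) -> list[LandmarkConfig]:
    """Average specimens into species (or species-morph) units.

    Specimens of a unit are Procrustes-superimposed among themselves and
    their aligned coordinates averaged; raw centroid sizes are averaged
    arithmetically and carried on the unit configuration.  Units from
    dimorphic species are suffixed ``_St`` / ``_Eu``.
    """
    units: dict[str, list[LandmarkConfig]] = {}
    for c in configs:
        units.setdefault(c.unit, []).append(c)
    out = []
    for label in units:
        members = units[label]
        if len(members) == 1:
            mean_coords = _normalize(members[0].coords)
        else:
            aligned = gpa(members).aligned
            mean_coords = aligned.mean(axis=0)
        mean_cs = float(np.mean([m.centroid_size for m in members]))
        ref = members[0]
        out.append(LandmarkConfig(specimen_id=label, coords=mean_coords,
                                  species=ref.species, morph=ref.morph,
                                  cs=mean_cs))
    return out


# --------------------------------------------------------------------------
# Form space and PCA
# --------------------------------------------------------------------------

def form_space(shape: ShapeCoords, sizes=None) -> pd.DataFrame:
    """Shape coordinates, optionally augmented by natural-log centroid size.

    With ``sizes`` (a Series or dict of raw centroid sizes, computed prior
    to scaling) the result is the 2k+1-column form matrix; without, the
    2k-column shape matrix.
    """
    X = shape.flat()
    if sizes is None:
        return X
    if isinstance(sizes, dict):
        sizes = pd.Series(sizes)
    sizes = sizes.reindex(X.index)
    if sizes.isna().any():
        missing = list(sizes.index[sizes.isna()])
        raise ValueError(f"missing centroid sizes for: {missing}")
    if (sizes <= 0).any():
        raise ValueError("centroid sizes must be positive")
    X = X.copy()
    X["logCS"] = np.log(sizes)
    return X


@dataclass
class PCResult:
    scores: pd.DataFrame          # units x axes
    loadings: pd.DataFrame        # variables x axes
    eigenvalues: np.ndarray       # non-increasing
    proportions: np.ndarray       # sums to 1 over all axes
    kind: str = "standard"        # or "phylogenetic"

    def n_axes_above(self, threshold: float) -> int:
        return int((self.proportions > threshold).sum())


def pca(X: pd.DataFrame) -> PCResult:
    """Covariance-matrix PCA on column-mean-centered data."""
    X = pd.DataFrame(X)
    if len(X) < 2:
        raise ValueError("PCA needs at least 2 units")
    M = X.to_numpy(dtype=float)
    centered = M - M.mean(axis=0)
    total = centered.var(axis=0, ddof=1).sum()
    if total == 0:
        raise ValueError("matrix has no variance")
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    n_axes = min(len(X) - 1, M.shape[1])
    eig = (s ** 2 / (len(X) - 1))[:n_axes]
    V = Vt[:n_axes].T
    axes = [f"PC{i + 1}" for i in range(n_axes)]
    return PCResult(
        scores=pd.DataFrame(centered @ V, index=X.index, columns=axes),
        loadings=pd.DataFrame(V, index=X.columns, columns=axes),
        eigenvalues=eig,
        proportions=eig / eig.sum(),
        kind="standard",
    )


def phylo_pca(X: pd.DataFrame, tree: Phylogeny) -> PCResult:
    """Phylogenetic PCA (GLS mean, evolutionary covariance eigenvectors).

    Rows of ``X`` must match the tree's tips exactly.  Deviations from the
    GLS mean under C (the shared path-length matrix) are decomposed via the
    C-weighted covariance; scores are the deviations projected onto its
    eigenvectors, so phylogenetic non-independence informs the axes.
    """
    X = pd.DataFrame(X)
    missing = [t for t in tree.tip_labels if t not in X.index]
    extra = [r for r in X.index if r not in tree.tip_labels]
    if missing or extra:
        raise ValueError(
            f"rows and tips do not match (missing {missing}, extra {extra})")
    X = X.loc[tree.tip_labels]
    M = X.to_numpy(dtype=float)
    n = len(X)
    C = tree.vcv()
    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    a = (one @ Cinv @ M) / (one @ Cinv @ one)
    D = M - a
    R = D.T @ Cinv @ D / (n - 1)
    eig, V = np.linalg.eigh(R)
    order = np.argsort(eig)[::-1]
    n_axes = min(n - 1, M.shape[1])
    eig, V = np.maximum(eig[order], 0)[:n_axes], V[:, order][:, :n_axes]
    axes = [f"PC{i + 1}" for i in range(n_axes)]
    return PCResult(
        scores=pd.DataFrame(D @ V, index=X.index, columns=axes),
        loadings=pd.DataFrame(V, index=X.columns, columns=axes),
        eigenvalues=eig,
        proportions=eig / eig.sum(),
        kind="phylogenetic",
    )
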