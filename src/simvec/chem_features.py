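"""Per-drug chemical feature vectors and the similarity metrics built on them.

Three profile families are supported, each paired with its natural metric:

* Morgan (circular) fingerprints, radius 3, folded to 100 bits — Tanimoto;
* RDKit molecular descriptors, the 100 with the most distinct values over the
  drug set, standardized — Gaussian kernel exp(-||X-Y||^2 / sigma^2);
* externally computed hyperbolic (hyperboloid-model) embeddings, read from a
  numeric table — Lorentz-distance similarity.

Profiles feed three consumers: node initialization of the embedding model,
similarity-edge weighting, and nearest-strong-neighbour lookup for
degree-conditioned negative-sampling caches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

MORGAN = "morgan"
DESCRIPTOR = "descriptor"
EXTERNAL = "external_embedding"

_METRIC_FOR_KIND = {MORGAN: "tanimoto", DESCRIPTOR: "gaussian", EXTERNAL: "lorentz"}


class FeaturizationError(ValueError):
    pass


@dataclass
class ChemProfileSet:
    """A matrix of per-drug feature vectors sharing one kind and length.

    ``matrix[i]`` is the vector of drug ``drug_ids[i]`` (entity ids).
    Morgan vectors are binary; descriptor vectors are standardized per column.
    """

    drug_ids: np.ndarray
    matrix: np.ndarray
    kind: str
    feature_names: list[str] | None = None

    def __post_init__(self):
        self.drug_ids = np.asarray(self.drug_ids, dtype=np.int64)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != len(self.drug_ids):
            raise ValueError("matrix rows must match drug_ids")
        if self.kind == MORGAN and not np.isin(self.matrix, (0.0, 1.0)).all():
            raise ValueError("morgan profiles must be binary")
        self._index = {int(d): i for i, d in enumerate(self.drug_ids)}
        self._max_lorentz: float | None = None

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def vector(self, drug: int) -> np.ndarray:
        """The drug's profile; drugs without one get the fallback (zero) vector."""
        i = self._index.get(int(drug))
        if i is None:
            warnings.warn(f"drug {drug} has no chemical profile; using fallback vector")
            return np.zeros(self.n_features)
        return self.matrix[i]

    def default_metric(self) -> str:
        return _METRIC_FOR_KIND[self.kind]

    def save(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, columns=self.feature_names)
        df.insert(0, "drug_id", self.drug_ids)
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

def _mol(smiles: str):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES: {smiles!r}")
    return mol


def morgan_profile(smiles: str, radius: int = 3, n_bits: int = 100) -> np.ndarray:
    """Folded circular fingerprint as a binary vector; deterministic per molecule."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(_mol(smiles))
    return np.array(fp, dtype=float)


def morgan_profiles(
    smiles_by_drug: Mapping[int, str | None], radius: int = 3, n_bits: int = 100
) -> ChemProfileSet:
    """Morgan profiles for a drug set; drugs lacking SMILES get the zero vector."""
    drug_ids = sorted(smiles_by_drug)
    rows, missing = [], []
    for d in drug_ids:
        smi = smiles_by_drug[d]
        if smi is None:
            missing.append(d)
            rows.append(np.zeros(n_bits))
        else:
            rows.append(morgan_profile(smi, radius, n_bits))
    if missing:
        logger.warning("%d drugs without SMILES received zero fingerprints", len(missing))
    return ChemProfileSet(np.array(drug_ids), np.array(rows), MORGAN)


def descriptor_profiles(
    smiles_by_drug: Mapping[int, str | None], n_keep: int = 100
) -> ChemProfileSet:
    """Standardized molecular-descriptor profiles.

    Computes the full RDKit descriptor panel, ranks descriptors by the number
    of distinct values over the drug set (ties alphabetically), keeps the top
    ``n_keep`` and standardizes each kept column to zero mean / unit variance.
    Drugs without SMILES sit at the column mean (zero after standardization).
    """
    drug_ids = sorted(smiles_by_drug)
    parsed = {d: smiles_by_drug[d] for d in drug_ids if smiles_by_drug[d] is not None}
    if len(parsed) < 2:
        raise FeaturizationError("need at least 2 drugs with valid SMILES")
    names = [n for n, _ in Descriptors.descList]
    table = pd.DataFrame(
        [Descriptors.CalcMolDescriptors(_mol(s)) for s in parsed.values()],
        index=list(parsed),
    )[names]
    table = table.replace([np.inf, -np.inf], np.nan).fillna(0.0)

    n_unique = table.nunique()
    if (n_unique <= 1).all():
        raise FeaturizationError("all descriptors constant over the drug set")
    ranked = sorted(names, key=lambda n: (-n_unique[n], n))
    if n_keep > len(ranked):
        warnings.warn(f"n_keep={n_keep} exceeds {len(ranked)} descriptors; keeping all")
        n_keep = len(ranked)
    kept = ranked[:n_keep]
    sub = table[kept].to_numpy(dtype=float)
    mean, std = sub.mean(axis=0), sub.std(axis=0)
    std[std == 0] = 1.0
    sub = (sub - mean) / std

    matrix = np.zeros((len(drug_ids), len(kept)))
    row_of = {d: i for i, d in enumerate(parsed)}
    for i, d in enumerate(drug_ids):
        if d in row_of:
            matrix[i] = sub[row_of[d]]
    return ChemProfileSet(np.array(drug_ids), matrix, DESCRIPTOR, feature_names=kept)


def load_external_profiles(table, n_dims: int | None = None) -> ChemProfileSet:
    """Read externally trained per-drug embeddings from a (drug_id, v0..vK) table."""
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep=None, engine="python")
    drug_ids = table.iloc[:, 0].astype(int).to_numpy()
    matrix = table.iloc[:, 1:].to_numpy(dtype=float)
    if n_dims is not None:
        matrix = matrix[:, :n_dims]
    return ChemProfileSet(drug_ids, matrix, EXTERNAL)


# ---------------------------------------------------------------------------
# similarity metrics
# ---------------------------------------------------------------------------

def tanimoto(x: np.ndarray, y: np.ndarray) -> float:
    """|X AND Y| / |X OR Y| for binary vectors; two all-zero vectors score 1."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    union = np.logical_or(x, y).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(x, y).sum() / union)


def gaussian_similarity(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Gaussian kernel exp(-||X - Y||^2 / sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    return float(np.exp(-np.sum((x - y) ** 2) / sigma**2))


def lorentz_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Lorentzian inner product -X0*Y0 + sum_{i>=1} Xi*Yi."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    return float(-x[0] * y[0] + x[1:] @ y[1:])


def max_lorentz_distance(profiles: ChemProfileSet) -> float:
    """max over drug pairs of the Lorentz distance, cached on the profile set."""
    if profiles._max_lorentz is None:
        m = profiles.matrix
        gram = -np.outer(m[:, 0], m[:, 0]) + m[:, 1:] @ m[:, 1:].T
        profiles._max_lorentz = float(gram.max())
    return profiles._max_lorentz


def lorentz_similarity(x: np.ndarray, y: np.ndarray, profiles: ChemProfileSet) -> float:
    """(max_pair lor_dist - lor_dist(X, Y)) / max_pair lor_dist.

    The normalizing maximum runs over all drug pairs of the profile set.  On a
    hyperboloid the self-distance is -1, so the value can exceed 1; it is
    reported unclipped.
    """
    mx = max_lorentz_distance(profiles)
    if mx == 0:
        raise ValueError("degenerate geometry: max Lorentz distance is 0")
    return float((mx - lorentz_distance(x, y)) / mx)


def similarity(x, y, metric: str, *, sigma: float | None = None,
               profiles: ChemProfileSet | None = None) -> float:
    if metric == "tanimoto":
        return tanimoto(x, y)
    if metric == "gaussian":
        if sigma is None:
            sigma = float(np.sqrt(len(np.asarray(x))))
        return gaussian_similarity(x, y, sigma)
    if metric == "lorentz":
        if profiles is None:
            raise ValueError("lorentz similarity needs the profile set")
        return lorentz_similarity(x, y, profiles)
    raise ValueError(f"unknown metric {metric!r}")


def nearest_strong_neighbor(
    drug: int, strong_set: Sequence[int], profiles: ChemProfileSet,
    external_ids: Mapping[int, str] | None = None,
) -> int:
    """The strong drug whose profile is Euclidean-closest to ``drug``'s.

    Ties are broken by ascending external_id (entity_id if none given).
    """
    strong = sorted(set(int(s) for s in strong_set))
    if not strong:
        raise ValueError("strong_set is empty")
    v = profiles.vector(drug)
    dists = [float(np.linalg.norm(profiles.vector(s) - v)) for s in strong]
    keyed = sorted(
        zip(dists, [external_ids[s] if external_ids else str(s) for s in strong], strong)
    )
    return keyed[0][2]
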