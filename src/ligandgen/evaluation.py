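"""Generation-quality metrics: validity, uniqueness, novelty, properties.

Metric conventions: identity is structure-level (canonical SMILES), so
"CCO" and "OCC" are one molecule; Unique@k is computed over the first k
valid molecules in generation order; novelty is the fraction of distinct
valid generated molecules absent from the (canonicalized) training
reference. Property distributions cover molecular weight, Crippen LogP,
QED, synthetic accessibility and natural-product likeness; similarity to
the training set uses Tanimoto on 2048-bit radius-2 Morgan fingerprints.
"""

from __future__ import annotations

import sys
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, Crippen, QED, RDConfig
from rdkit.Chem import rdFingerprintGenerator
from rdkit.DataStructs import BulkTanimotoSimilarity, TanimotoSimilarity

RDLogger.DisableLog("rdApp.*")

for _sub in ("SA_Score", "NP_Score"):
    _p = os.path.join(RDConfig.RDContribDir, _sub)
    if _p not in sys.path:
        sys.path.append(_p)
import sascorer  # noqa: E402  (rdkit contrib)
import npscorer  # noqa: E402

_NP_MODEL = None


def _np_model():
    global _NP_MODEL
    if _NP_MODEL is None:
        _NP_MODEL = npscorer.readNPModel()
    return _NP_MODEL


_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def canonicalize(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


@dataclass
class ReferenceSet:
    """Canonicalized training-set SMILES with a fingerprint cache."""

    canonical: list[str]
    _fps: list | None = field(default=None, repr=False)

    @classmethod
    def from_smiles(cls, smiles: list[str]) -> "ReferenceSet":
        seen = set()
        out = []
        for s in smiles:
            c = canonicalize(s)
            if c is not None and c not in seen:
                seen.add(c)
                out.append(c)
        return cls(canonical=out)

    def __contains__(self, canonical_smiles: str) -> bool:
        return canonical_smiles in set(self.canonical)

    @property
    def fingerprints(self):
        if self._fps is None:
            self._fps = [_FP_GEN.GetFingerprint(Chem.MolFromSmiles(s))
                         for s in self.canonical]
        return self._fps


def validity(smiles: list[str]) -> tuple[float, list[str]]:
    """Fraction of parseable strings and the valid sublist (original order)."""
    if not smiles:
        warnings.warn("validity of an empty list is undefined")
        return float("nan"), []
    valid = [s for s in smiles if Chem.MolFromSmiles(s) is not None]
    return len(valid) / len(smiles), valid


def unique_at_k(smiles: list[str], k: int) -> float:
    """Distinct canonical structures among the first k valid molecules / k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    _, valid = validity(smiles) if smiles else (float("nan"), [])
    first = valid[:k]
    if len(first) < k:
        warnings.warn(f"only {len(first)} valid molecules available for k={k}")
        k = len(first)
    if k == 0:
        return float("nan")
    return len({canonicalize(s) for s in first}) / k


def novelty(generated: list[str], reference: ReferenceSet) -> float:
    """Fraction of distinct valid generated molecules not in the reference."""
    if not generated:
        raise ValueError("novelty of an empty generated list")
    if not reference.canonical:
        warnings.warn("empty reference set: novelty is trivially 1")
        return 1.0
    distinct = {canonicalize(s) for s in generated}
    distinct.discard(None)
    if not distinct:
        return float("nan")
    ref = set(reference.canonical)
    return sum(1 for s in distinct if s not in ref) / len(distinct)


def property_table(valid_smiles: list[str]) -> pd.DataFrame:
    """Per-molecule MW, LogP, QED, SAscore, NP-likeness (valid inputs only)."""
    rows = []
    for s in valid_smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"property_table expects valid SMILES, got {s!r}")
        row = {"smiles": s, "flagged": False}
        try:
            row["MW"] = Descriptors.MolWt(mol)
            row["LogP"] = Crippen.MolLogP(mol)
            row["QED"] = QED.qed(mol)
            row["SAscore"] = sascorer.calculateScore(mol)
            row["NPlikeness"] = npscorer.scoreMol(mol, _np_model())
        except Exception:
            row["flagged"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def tanimoto_profile(query: str, reference: ReferenceSet) -> tuple[np.ndarray, float]:
    """Similarity of one molecule to every reference molecule, plus the max."""
    mol = Chem.MolFromSmiles(query)
    if mol is None:
        raise ValueError(f"query does not parse: {query!r}")
    fp = _FP_GEN.GetFingerprint(mol)
    sims = np.asarray(BulkTanimotoSimilarity(fp, reference.fingerprints))
    return sims, float(sims.max()) if sims.size else float("nan")


def tanimoto_pair(a: str, b: str) -> float:
    fa = _FP_GEN.GetFingerprint(Chem.MolFromSmiles(a))
    fb = _FP_GEN.GetFingerprint(Chem.MolFromSmiles(b))
    return float(TanimotoSimilarity(fa, fb))


@dataclass
class MetricsReport:
    n_generated: int
    n_evaluated: int
    valid: float
    unique_at_k: dict[int, float]
    novelty: float
    properties: pd.DataFrame
    max_tanimoto_to_train: list[float]

    def to_dict(self) -> dict:
        return {
            "n_generated": self.n_generated,
            "n_evaluated": self.n_evaluated,
            "valid": self.valid,
            "unique_at_k": {str(k): v for k, v in self.unique_at_k.items()},
            "novelty": self.novelty,
            "property_means": {
                c: float(self.properties[c].mean())
                for c in ("MW", "LogP", "QED", "SAscore", "NPlikeness")
                if c in self.properties and len(self.properties)},
            "max_tanimoto_to_train": {
                "mean": float(np.mean(self.max_tanimoto_to_train))
                if self.max_tanimoto_to_train else float("nan"),
                "max": float(np.max(self.max_tanimoto_to_train))
                if self.max_tanimoto_to_train else float("nan"),
            },
        }


def evaluate_run(generated: list[str], reference: ReferenceSet,
                 ks: tuple[int, ...] = (1000, 10000),
                 sample_size: int = 30000, seed: int = 0,
                 with_tanimoto: bool = True) -> MetricsReport:
    """Full metric sweep over a seeded subsample of a generation run."""
    rng = np.random.default_rng(seed)
    if sample_size < len(generated):
        idx = sorted(rng.choice(len(generated), size=sample_size, replace=False))
        sample = [generated[i] for i in idx]
    else:
        if sample_size > len(generated):
            warnings.warn("sample_size exceeds the generated list; using all")
        sample = list(generated)
    frac, valid = validity(sample)
    uniq = {k: unique_at_k(sample, k) for k in ks}
    nov = novelty(sample, reference) if sample else float("nan")
    distinct_valid = list(dict.fromkeys(canonicalize(s) for s in valid))
    props = property_table(distinct_valid)
    tani = []
    if with_tanimoto and reference.canonical:
        for s in distinct_valid:
            _, mx = tanimoto_profile(s, reference)
            tani.append(mx)
    return MetricsReport(
        n_generated=len(generated), n_evaluated=len(sample), valid=frac,
        unique_at_k=uniq, novelty=nov, properties=props,
        max_tanimoto_to_train=tani)


def plot_property_histograms(report: MetricsReport, path: str) -> None:
    """Histogram panel of the five property distributions."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    cols = ["MW", "LogP", "QED", "SAscore", "NPlikeness"]
    fig, axes = plt.subplots(1, len(cols), figsize=(4 * len(cols), 3))
    for ax, c in zip(axes, cols):
        if c in report.properties:
            ax.hist(report.properties[c].dropna(), bins=30)
        ax.set_title(c)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
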