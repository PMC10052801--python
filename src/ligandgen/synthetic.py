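"""Synthetic fixtures: condition-linked molecule families and latent clouds.

The generator emulates the statistical structure the conditional model
assumes: a handful of protein "targets", each with (a) a recognisable
repeated sequence motif, (b) a family of molecules sharing a scaffold, and
(c) a known isotropic Gaussian in latent space centred on its own simplex
vertex. Ground-truth latent parameters make conditional-recovery
experiments checkable against stated means.

Everything is deterministic under the seed argument.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .vocab import AMINO_ACIDS, SmilesVocabulary
from . import io as lio

#: scaffolds assigned to targets in order; the leading entries are chosen
#: chemically distinct (aromatic carbocycle / S-heteroaromatic / saturated
#: N-heterocycle ...) so neighbouring targets' families separate in latent
#: space; all tokenize under the vocabulary
SCAFFOLDS: tuple[str, ...] = (
    "c1ccccc1",      # benzene
    "c1ccsc1",       # thiophene
    "C1CCNCC1",      # piperidine
    "c1ccncc1",      # pyridine
    "C1CCCCC1",      # cyclohexane
    "c1cc[nH]c1",    # pyrrole
    "C1CCOC1",       # tetrahydrofuran
    "c1cncnc1",      # pyrimidine
    "c1ccoc1",       # furan
    "c1c[nH]cn1",    # imidazole
)

#: substituents used to decorate scaffolds (attachment at their first atom);
#: short groups keep fixture SMILES compact (max 14 tokens on the bundled
#: scaffolds) so sequence models converge at desk scale
SUBSTITUENTS: tuple[str, ...] = (
    "C", "N", "O", "F", "Cl", "CC", "CO", "CN",
)


@dataclass
class SyntheticTarget:
    target_id: str
    sequence: str
    latent_mean: np.ndarray
    latent_cov_scale: float
    molecule_family: list[str]


@dataclass
class SyntheticCorpus:
    pairs: list[tuple[str, str, float]]  # (smiles, sequence, activity)
    targets: list[SyntheticTarget]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        seq_to_id = {t.sequence: t.target_id for t in self.targets}
        for smi, seq, act in self.pairs:
            rows.append((smi, seq, act, seq_to_id[seq]))
        return pd.DataFrame(rows, columns=["smiles", "sequence", "activity", "target_id"])

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "pairs.csv", index=False)
        lio.write_fasta(out / "targets.fasta",
                        {t.target_id: t.sequence for t in self.targets})
        lio.write_json(out / "targets.json", {
            t.target_id: {
                "sequence": t.sequence,
                "latent_mean": [float(x) for x in t.latent_mean],
                "latent_cov_scale": t.latent_cov_scale,
                "molecule_family": t.molecule_family,
            } for t in self.targets})


def _attach(scaffold: Chem.Mol, sites_and_subs: list[tuple[int, str]]) -> str | None:
    """Attach substituents (by their first atom) at scaffold atom indices."""
    mol = Chem.RWMol(scaffold)
    for site, sub in sites_and_subs:
        frag = Chem.MolFromSmiles(sub)
        if frag is None:
            return None
        offset = mol.GetNumAtoms()
        mol.InsertMol(frag)
        mol.AddBond(site, offset, Chem.BondType.SINGLE)
    try:
        out = mol.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return Chem.MolToSmiles(out)


def make_toy_smiles_family(scaffold: str, n: int, seed: int) -> list[str]:
    """``n`` distinct valid SMILES built by decorating ``scaffold``.

    The scaffold itself (canonicalized) comes first; the rest enumerate
    single then paired substituent attachments in a seeded order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = Chem.MolFromSmiles(scaffold)
    if base is None:
        raise ValueError(f"scaffold does not parse: {scaffold!r}")
    vocab = SmilesVocabulary()
    canon0 = Chem.MolToSmiles(base)
    family = [canon0]
    seen = {canon0}
    if n == 1:
        return family

    rng = np.random.default_rng(seed)
    sites = [a.GetIdx() for a in base.GetAtoms() if a.GetTotalNumHs() > 0]
    singles = [[(s, sub)] for s in sites for sub in SUBSTITUENTS]
    doubles = [[(s1, u1), (s2, u2)]
               for s1, s2 in itertools.combinations(sites, 2)
               for u1 in SUBSTITUENTS for u2 in SUBSTITUENTS]
    candidates = singles + doubles
    order = rng.permutation(len(candidates))
    for idx in order:
        smi = _attach(base, candidates[idx])
        if smi is None or smi in seen or vocab.try_tokenize(smi) is None:
            continue
        seen.add(smi)
        family.append(smi)
        if len(family) == n:
            return family
    raise ValueError(
        f"could not enumerate {n} distinct molecules on scaffold {scaffold!r}")


def simplex_means(n_targets: int, latent_dim: int, separation: float) -> np.ndarray:
    """Regular-simplex latent means with pairwise distance ``separation``."""
    if n_targets == 1:
        return np.zeros((1, latent_dim))
    if latent_dim < n_targets - 1:
        raise ValueError(
            f"latent_dim={latent_dim} cannot host a {n_targets}-point simplex "
            f"(needs >= {n_targets - 1})")
    e = np.eye(n_targets)
    centered = e - e.mean(axis=0)
    # orthonormal basis of the centered subspace -> coordinates in R^(n-1)
    u, s, _ = np.linalg.svd(centered.T, full_matrices=False)
    coords = centered @ u[:, :n_targets - 1]
    coords *= separation / np.sqrt(2.0)
    means = np.zeros((n_targets, latent_dim))
    means[:, :n_targets - 1] = coords
    return means


def _motif_sequence(rng: np.random.Generator, length: int, motif_len: int = 6) -> str:
    motif = "".join(rng.choice(list(AMINO_ACIDS), size=motif_len))
    reps = length // motif_len + 1
    return (motif * reps)[:length]


def make_synthetic_corpus(n_targets: int, mols_per_target: int,
                          latent_dim: int, separation: float, seed: int,
                          latent_cov_scale: float = 0.5) -> SyntheticCorpus:
    """Build a corpus of condition-linked molecule families.

    Each target owns a scaffold family of ``mols_per_target`` molecules, a
    motif protein sequence of length 30-100, and a ground-truth latent
    Gaussian N(mean_t, scale^2 I) with the means on a regular simplex of
    edge ``separation``.
    """
    if min(n_targets, mols_per_target, latent_dim) < 1:
        raise ValueError("all counts must be >= 1")
    if n_targets > len(SCAFFOLDS):
        raise ValueError(f"at most {len(SCAFFOLDS)} targets supported")
    rng = np.random.default_rng(seed)
    means = simplex_means(n_targets, latent_dim, separation)

    targets: list[SyntheticTarget] = []
    pairs: list[tuple[str, str, float]] = []
    for t in range(n_targets):
        seq = _motif_sequence(rng, int(rng.integers(30, 101)))
        family = make_toy_smiles_family(
            SCAFFOLDS[t], mols_per_target, int(rng.integers(0, 2 ** 31)))
        # distinct uniforms -> per-target median well-defined, labels predictable
        acts = rng.uniform(0.0, 1.0, size=mols_per_target)
        while len(np.unique(acts)) != mols_per_target:  # pragma: no cover
            acts = rng.uniform(0.0, 1.0, size=mols_per_target)
        targets.append(SyntheticTarget(
            target_id=f"T{t:02d}", sequence=seq,
            latent_mean=means[t], latent_cov_scale=latent_cov_scale,
            molecule_family=family))
        for smi, act in zip(family, acts):
            pairs.append((smi, seq, float(act)))
    return SyntheticCorpus(pairs=pairs, targets=targets, seed=seed)


def make_motif_variants(sequence: str, n: int, seed: int,
                        sub_rate: float = 0.05) -> list[str]:
    """Noisy variants of a motif sequence (point substitutions + crops).

    Gives each synthetic target a small family of related sequences so that
    sequence-embedding experiments have within-family structure to learn.
    """
    rng = np.random.default_rng(seed)
    aas = list(AMINO_ACIDS)
    out = []
    for _ in range(n):
        chars = list(sequence)
        k = rng.binomial(len(chars), sub_rate)
        for i in rng.choice(len(chars), size=k, replace=False):
            chars[i] = str(rng.choice(aas))
        lo = int(rng.integers(0, max(1, len(chars) // 10)))
        hi = len(chars) - int(rng.integers(0, max(1, len(chars) // 10)))
        out.append("".join(chars[lo:hi]))
    return out


def sample_conditional_latents(target: SyntheticTarget, n: int, seed: int) -> np.ndarray:
    """i.i.d. draws from the target's ground-truth latent Gaussian."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mean = np.asarray(target.latent_mean, dtype=float)
    return mean + target.latent_cov_scale * rng.standard_normal((n, mean.size))
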