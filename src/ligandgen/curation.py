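"""Dataset curation: activity binarization, SMILES sanitization, filtering.

Raw drug–target activity tables are reduced to a clean training corpus in a
fixed rule order:

1. per-target median binarization of the activity value (strictly greater
   than the median → label 1, otherwise 0);
2. removal of label-0 rows;
3. SMILES sanitization (drop salts, strip stereochemistry, canonicalize;
   reject unparseable or inorganic structures and uncommon atoms);
4. rejection of strings that do not tokenize under the 29-token alphabet;
5. rejection of proteins with residues outside the 22-letter alphabet
   (in particular the unknown residue X);
6. deduplication of identical (SMILES, sequence) pairs.

Every dropped row is accounted for in a :class:`CurationLedger`, so
``n_in == n_out + sum(dropped)`` always holds.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .vocab import ProteinVocabulary, SmilesVocabulary

RDLogger.DisableLog("rdApp.*")

#: elements covered by the SMILES token set; anything else is "uncommon"
ALLOWED_ELEMENTS = frozenset({"C", "N", "S", "O", "F", "Cl", "Br", "H"})

#: sentinel returned by :func:`sanitize_smiles` for rejected structures
REJECT = None


@dataclass
class DrugTargetPair:
    """One curated corpus row."""

    smiles: str
    sequence: str
    activity: float
    label: int
    target_id: str = ""


@dataclass
class CurationLedger:
    """Per-rule drop counters; conserves the input row count."""

    n_in: int = 0
    n_out: int = 0
    dropped: dict[str, int] = field(default_factory=lambda: {
        "label_zero": 0,
        "invalid_smiles": 0,
        "inorganic": 0,
        "uncommon_atom": 0,
        "untokenizable": 0,
        "protein_rejected": 0,
        "duplicate": 0,
    })

    def drop(self, rule: str, n: int = 1) -> None:
        self.dropped[rule] += n

    @property
    def conserves(self) -> bool:
        return self.n_in == self.n_out + sum(self.dropped.values())

    def to_dict(self) -> dict:
        return {"n_in": self.n_in, "n_out": self.n_out, "dropped": dict(self.dropped)}


def binarize_activity(records: list[tuple[str, float]],
                      ties_to_zero: bool = True) -> list[tuple[str, int]]:
    """Label each (target_id, activity) record against its target's median.

    A record is labelled 1 iff its activity strictly exceeds the sample
    median of its own target's activities; values equal to the median get 0
    (``ties_to_zero=False`` flips ties to 1 for sensitivity analyses).
    """
    if not records:
        return []
    by_target: dict[str, list[float]] = {}
    for tid, act in records:
        by_target.setdefault(tid, []).append(float(act))
    medians = {tid: float(np.median(v)) for tid, v in by_target.items()}
    out = []
    for tid, act in records:
        m = medians[tid]
        if ties_to_zero:
            label = int(float(act) > m)
        else:
            label = int(float(act) >= m)
        out.append((tid, label))
    return out


def _strip_salts(mol: Chem.Mol) -> Chem.Mol:
    """Keep the largest fragment by heavy-atom count.

    Ties break on the lexicographically smallest canonical SMILES, so the
    choice is reproducible.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    keyed = []
    for f in frags:
        try:
            smi = Chem.MolToSmiles(f)
        except Exception:
            smi = ""
        keyed.append((-f.GetNumHeavyAtoms(), smi, f))
    keyed.sort(key=lambda t: (t[0], t[1]))
    return keyed[0][2]


def sanitize_smiles(smiles: str, ledger: CurationLedger | None = None) -> str | None:
    """Sanitize one SMILES string; returns canonical SMILES or ``None``.

    Rejections (and their ledger rule): unparseable or empty input
    (``invalid_smiles``); no carbon after salt stripping (``inorganic``);
    elements outside the token set (``uncommon_atom``). Stereochemistry is
    erased before canonicalization.
    """
    def reject(rule: str):
        if ledger is not None:
            ledger.drop(rule)
        return REJECT

    if not smiles or not isinstance(smiles, str):
        return reject("invalid_smiles")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return reject("invalid_smiles")
    mol = _strip_salts(mol)
    if not any(a.GetSymbol() == "C" for a in mol.GetAtoms()):
        return reject("inorganic")
    if any(a.GetSymbol() not in ALLOWED_ELEMENTS for a in mol.GetAtoms()):
        return reject("uncommon_atom")
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def tokenize_smiles(smiles: str, vocab: SmilesVocabulary | None = None) -> list[str] | None:
    """Greedy longest-match tokenization; ``None`` if any symbol is unknown."""
    vocab = vocab or SmilesVocabulary()
    return vocab.try_tokenize(smiles)


def filter_protein(sequence: str, vocab: ProteinVocabulary | None = None) -> bool:
    """True iff the sequence is non-empty and uses only the 22-letter alphabet."""
    vocab = vocab or ProteinVocabulary()
    return isinstance(sequence, str) and vocab.accepts(sequence)


def curate(table: pd.DataFrame,
           keep_label_zero: bool = False,
           ties_to_zero: bool = True) -> tuple[list[DrugTargetPair], CurationLedger]:
    """Run the full curation chain on a raw pair table.

    ``table`` needs columns ``smiles``, ``sequence``, ``activity`` and
    optionally ``target_id`` (defaults to the sequence itself, i.e. one
    target per distinct protein).
    """
    required = {"smiles", "sequence", "activity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"input table is missing columns: {sorted(missing)}")

    df = table.copy()
    if "target_id" not in df.columns:
        df["target_id"] = df["sequence"]

    ledger = CurationLedger(n_in=len(df))
    smiles_vocab = SmilesVocabulary()
    protein_vocab = ProteinVocabulary()

    labels = binarize_activity(
        list(zip(df["target_id"].astype(str), df["activity"].astype(float))),
        ties_to_zero=ties_to_zero)
    df["label"] = [lab for _, lab in labels]

    out: list[DrugTargetPair] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        if not keep_label_zero and row.label == 0:
            ledger.drop("label_zero")
            continue
        canon = sanitize_smiles(row.smiles, ledger)
        if canon is REJECT:
            continue
        if smiles_vocab.try_tokenize(canon) is None:
            ledger.drop("untokenizable")
            continue
        if not filter_protein(str(row.sequence), protein_vocab):
            ledger.drop("protein_rejected")
            continue
        key = (canon, str(row.sequence))
        if key in seen:
            ledger.drop("duplicate")
            continue
        seen.add(key)
        out.append(DrugTargetPair(
            smiles=canon, sequence=str(row.sequence),
            activity=float(row.activity), label=int(row.label),
            target_id=str(row.target_id)))

    ledger.n_out = len(out)
    assert ledger.conserves
    return out, ledger


def pairs_to_frame(pairs: list[DrugTargetPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.smiles, p.sequence, p.activity, p.label, p.target_id) for p in pairs],
        columns=["smiles", "sequence", "activity", "label", "target_id"])
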