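"""Post-screen compound triage.

Implements the filter cascade applied after the ranked virtual screen:

1. keep the ``top_k`` ranked compounds (default 30,000);
2. drop compounds with molecular weight <= 200 Da;
3. drop compounds matching any exclusion SMARTS pattern;
4. cluster the survivors by ECFP4 fingerprint at a Tanimoto similarity
   cutoff (default 0.35) with the Butina greedy sphere-exclusion
   procedure and keep one representative per cluster;
5. keep representatives with MW < 500 Da, cLogP < 5 and no PAINS match.

Also provides the Lipinski and Veber drug-likeness rule engines over a
descriptor set. Descriptors and substructure matching are computed with
RDKit; the Butina procedure itself is implemented here with explicit,
deterministic tie-breaking (descending neighbor count, ties by
lexicographic id).

The original workflow additionally used proprietary PAINS/toxicology
scores; here PAINS is public substructure matching (pass = no matches)
and toxicity is an optional external score column hook.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

from .chemio import MolGraph

__all__ = [
    "DescriptorSet",
    "Fingerprint",
    "TriageConfig",
    "ClusterSet",
    "TriageReport",
    "descriptors",
    "lipinski_violations",
    "veber_violations",
    "ecfp4",
    "tanimoto",
    "butina_cluster",
    "smarts_filter",
    "pains_matches",
    "triage_pipeline",
    "load_smarts_file",
    "default_exclusion_patterns",
]


@dataclass(frozen=True)
class DescriptorSet:
    """Drug-likeness descriptors of one compound."""

    mw: float        # molecular weight, Da
    clogp: float     # Crippen octanol-water logP
    hba: int         # H-bond acceptors, Lipinski N+O count
    hbd: int         # H-bond donors, Lipinski NH+OH count
    n_rot: int       # rotatable bonds (amide C-N excluded)
    tpsa: float      # Ertl topological polar surface area, A^2

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("mw must be > 0")
        if min(self.hba, self.hbd, self.n_rot) < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class Fingerprint:
    """Fixed-length hashed circular fingerprint (ECFP4: radius 2)."""

    bits: np.ndarray  # bool array of length n_bits
    radius: int = 2

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)

    @property
    def n_bits(self) -> int:
        return self.bits.size

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


@dataclass(frozen=True)
class TriageConfig:
    """Thresholds of the five-stage cascade. Inequalities are strict for
    mw_min (>), mw_max (<) and logp_max (<), matching the printed rules."""

    top_k: int = 30000
    mw_min: float = 200.0
    smarts_patterns: tuple[str, ...] = ()
    butina_cutoff: float = 0.35
    mw_max: float = 500.0
    logp_max: float = 5.0
    pains_max_matches: int = 0

    def __post_init__(self) -> None:
        # values > 1 are permitted and make every compound a singleton
        # cluster (no pair can reach the cutoff), disabling stage 4
        if self.butina_cutoff < 0:
            raise ValueError("butina_cutoff must be >= 0")


@dataclass
class ClusterSet:
    """Butina clusters: (representative id, member ids) pairs.

    Members include the representative; clusters partition the input.
    """

    clusters: list[tuple[str, list[str]]]

    @property
    def representatives(self) -> list[str]:
        return [rep for rep, _ in self.clusters]

    def assignment(self) -> dict[str, str]:
        return {m: rep for rep, members in self.clusters for m in members}


# ---------------------------------------------------------------------------
# Descriptors and rules
# ---------------------------------------------------------------------------

def _as_mol(mol: MolGraph | Chem.Mol) -> Chem.Mol:
    if isinstance(mol, Chem.Mol):
        return mol
    return mol.to_rdkit()


def descriptors(mol: MolGraph | Chem.Mol) -> DescriptorSet:
    """Compute the six rule-engine descriptors (RDKit conventions)."""
    m = _as_mol(mol)
    return DescriptorSet(
        mw=float(Descriptors.MolWt(m)),
        clogp=float(Crippen.MolLogP(m)),
        hba=int(Lipinski.NOCount(m)),
        hbd=int(Lipinski.NHOHCount(m)),
        n_rot=int(Descriptors.NumRotatableBonds(m)),
        tpsa=float(Descriptors.TPSA(m)),
    )


def lipinski_violations(d: DescriptorSet) -> list[str]:
    """Names of violated Lipinski criteria: MW < 500, cLogP < 5,
    HBA < 10, HBD < 5 (all strict, exactly as printed)."""
    out = []
    if not d.mw < 500:
        out.append("mw")
    if not d.clogp < 5:
        out.append("clogp")
    if not d.hba < 10:
        out.append("hba")
    if not d.hbd < 5:
        out.append("hbd")
    return out


def veber_violations(d: DescriptorSet) -> list[str]:
    """Names of violated Veber criteria: nRot <= 10, HBA+HBD < 12,
    TPSA <= 140 A^2."""
    out = []
    if not d.n_rot <= 10:
        out.append("n_rot")
    if not d.hba + d.hbd < 12:
        out.append("hba_hbd_sum")
    if not d.tpsa <= 140:
        out.append("tpsa")
    return out


# ---------------------------------------------------------------------------
# Fingerprints and clustering
# ---------------------------------------------------------------------------

def ecfp4(mol: MolGraph | Chem.Mol, n_bits: int = 2048) -> Fingerprint:
    """ECFP4 (Morgan radius-2) fingerprint hashed to ``n_bits``."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    arr = np.array(gen.GetFingerprintAsNumPy(_as_mol(mol)), dtype=bool)
    return Fingerprint(bits=arr)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a & b| / |a | b|; defined as 1.0 when both are empty."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint lengths differ: {a.n_bits} vs {b.n_bits}")
    union = int(np.count_nonzero(a.bits | b.bits))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(a.bits & b.bits)) / union


def butina_cluster(fps: Mapping[str, Fingerprint], cutoff: float) -> ClusterSet:
    """Greedy sphere-exclusion (Butina) clustering.

    Neighbors are pairs with Tanimoto similarity >= ``cutoff``. Ids are
    ordered by descending neighbor count (ties broken by lexicographic
    id); the sweep repeatedly takes the first unassigned id as a cluster
    representative, which claims all its still-unassigned neighbors.
    """
    if not fps:
        raise ValueError("butina_cluster needs at least one fingerprint")
    ids = sorted(fps)
    mat = np.stack([fps[i].bits for i in ids]).astype(np.float32)
    inter = mat @ mat.T
    pops = mat.sum(axis=1)
    union = pops[:, None] + pops[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-12), 1.0)
    neighbor = sim >= cutoff
    np.fill_diagonal(neighbor, False)
    counts = neighbor.sum(axis=1)
    order = sorted(range(len(ids)), key=lambda k: (-counts[k], ids[k]))

    assigned: set[int] = set()
    clusters: list[tuple[str, list[str]]] = []
    for k in order:
        if k in assigned:
            continue
        members = [k] + [j for j in np.nonzero(neighbor[k])[0]
                         if j not in assigned and j != k]
        assigned.update(members)
        clusters.append((ids[k], sorted(ids[j] for j in members)))
    return ClusterSet(clusters=clusters)


# ---------------------------------------------------------------------------
# Substructure filters
# ---------------------------------------------------------------------------

def load_smarts_file(path: str | Path) -> list[str]:
    """Read a SMARTS pattern file: one pattern per line, '#' comments,
    optional whitespace-separated label after the pattern."""
    patterns = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        patterns.append(line.split()[0])
    return patterns


def default_exclusion_patterns() -> list[str]:
    """The shipped, editable exclusion list (reactive/undesirable moieties)."""
    ref = resources.files("voxscreen.data") / "exclusion_smarts.txt"
    with resources.as_file(ref) as path:
        return load_smarts_file(path)


def _compile_patterns(patterns: Sequence[str]) -> list[tuple[str, Chem.Mol]]:
    compiled = []
    for p in patterns:
        q = Chem.MolFromSmarts(p)
        if q is None:
            raise ValueError(f"invalid SMARTS pattern {p!r}")
        compiled.append((p, q))
    return compiled


def smarts_filter(mols: Sequence[MolGraph], patterns: Sequence[str]
                  ) -> tuple[list[MolGraph], list[tuple[MolGraph, str]]]:
    """Partition molecules into (retained, excluded-with-matched-pattern).

    A molecule is excluded if any pattern matches as a substructure; the
    first matching pattern (file order) is recorded.
    """
    compiled = _compile_patterns(patterns)
    retained, excluded = [], []
    for mol in mols:
        m = _as_mol(mol)
        hit = next((p for p, q in compiled if m.HasSubstructMatch(q)), None)
        if hit is None:
            retained.append(mol)
        else:
            excluded.append((mol, hit))
    return retained, excluded


_PAINS_CATALOG: FilterCatalog | None = None


def _pains_catalog() -> FilterCatalog:
    global _PAINS_CATALOG
    if _PAINS_CATALOG is None:
        params = FilterCatalogParams()
        params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS)
        _PAINS_CATALOG = FilterCatalog(params)
    return _PAINS_CATALOG


def pains_matches(mol: MolGraph | Chem.Mol,
                  pains_set: Sequence[str] | None = None) -> int:
    """Number of distinct PAINS patterns matching the molecule.

    With ``pains_set=None`` the public PAINS A/B/C families shipped with
    RDKit are used; otherwise the given SMARTS list. Default pass = 0.
    """
    m = _as_mol(mol)
    if pains_set is None:
        return len(_pains_catalog().GetMatches(m))
    compiled = _compile_patterns(pains_set)
    return sum(1 for _, q in compiled if m.HasSubstructMatch(q))


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------

@dataclass
class TriageReport:
    """Outcome of the cascade: per-stage counts plus a full audit trail."""

    stage_counts: dict[str, int]
    survivors: list[str]
    audit: pd.DataFrame  # one row per input compound
    clusters: ClusterSet | None = None

    def to_csv(self, path: str | Path) -> None:
        self.audit.to_csv(path, index=False)

    def summary_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"stage_counts": self.stage_counts,
             "n_survivors": len(self.survivors)}, indent=1))


STAGES = ["input", "top_k", "mw_min", "smarts", "cluster_reps", "final_filters"]


def triage_pipeline(ranked: Sequence[str], mols: Mapping[str, MolGraph],
                    cfg: TriageConfig = TriageConfig(),
                    tox_scores: Mapping[str, float] | None = None,
                    tox_max: float | None = None) -> TriageReport:
    """Run the five-stage cascade over a ranked compound list.

    ``ranked`` is the screen output, best first. ``tox_scores``/``tox_max``
    form an optional hook for an externally supplied toxicity score column
    applied with the final filters; by default no toxicity filter runs.
    Survivor sets are non-increasing along the cascade by construction.
    """
    missing = [i for i in ranked if i not in mols]
    if missing:
        raise KeyError(f"ranked ids missing from molecule map: {missing[:5]}")

    audit = pd.DataFrame({"compound_id": list(ranked)})
    audit["rank"] = np.arange(1, len(ranked) + 1)

    # stage 1: top-K by rank
    stage1 = list(ranked[:cfg.top_k])
    audit["pass_top_k"] = audit["rank"] <= cfg.top_k

    # stage 2: MW > mw_min (strict)
    desc = {i: descriptors(mols[i]) for i in stage1}
    stage2 = [i for i in stage1 if desc[i].mw > cfg.mw_min]
    audit["mw"] = [desc[i].mw if i in desc else np.nan
                   for i in audit["compound_id"]]
    s2 = set(stage2)
    audit["pass_mw_min"] = audit["compound_id"].isin(s2)

    # stage 3: exclusion SMARTS
    retained, excluded = smarts_filter([mols[i] for i in stage2],
                                       cfg.smarts_patterns)
    matched = {m.id: pat for m, pat in excluded}
    stage3 = [m.id for m in retained]
    audit["excluded_smarts"] = [matched.get(i, "") for i in audit["compound_id"]]
    audit["pass_smarts"] = audit["compound_id"].isin(set(stage3))

    # stage 4: ECFP4 + Butina, keep representatives
    clusters: ClusterSet | None = None
    if stage3:
        fps = {i: ecfp4(mols[i]) for i in stage3}
        clusters = butina_cluster(fps, cfg.butina_cutoff)
        stage4 = sorted(clusters.representatives)
        assign = clusters.assignment()
        audit["cluster_rep"] = [assign.get(i, "") for i in audit["compound_id"]]
    else:
        stage4 = []
        audit["cluster_rep"] = ""
    audit["pass_cluster_rep"] = audit["compound_id"].isin(set(stage4))

    # stage 5: final property filters on representatives
    stage5 = []
    for i in stage4:
        d = desc[i]
        ok = d.mw < cfg.mw_max and d.clogp < cfg.logp_max
        ok = ok and pains_matches(mols[i]) <= cfg.pains_max_matches
        if ok and tox_scores is not None and tox_max is not None:
            ok = tox_scores.get(i, 0.0) < tox_max
        if ok:
            stage5.append(i)
    audit["pass_final"] = audit["compound_id"].isin(set(stage5))

    counts = {
        "input": len(ranked),
        "top_k": len(stage1),
        "mw_min": len(stage2),
        "smarts": len(stage3),
        "cluster_reps": len(stage4),
        "final_filters": len(stage5),
    }
    return TriageReport(stage_counts=counts, survivors=stage5,
                        audit=audit, clusters=clusters)
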