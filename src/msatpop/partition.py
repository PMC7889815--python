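"""Post-processing of admixture-clustering output.

Given replicate log-probabilities over a range of cluster numbers and an
individual ancestry (Q) matrix, these routines pick the number of clusters by
Evanno's second-difference criterion, classify individuals as genetically
pure (max q >= 0.9) or introgressed, summarize populations by their
proportion of pure individuals (Qp), and partition populations into two
"pure" groups plus one "admixed" group (Qp >= 0.8 rule, boundary inclusive).
The clustering MCMC itself is out of scope: Q-matrices are inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import QMatrix

__all__ = [
    "evanno_delta_k",
    "classify_individuals",
    "population_qp",
    "partition_populations",
    "GroupPartition",
]


def evanno_delta_k(lnp: pd.DataFrame) -> pd.DataFrame:
    """Evanno table from a K x replicate matrix of ln P(K).

    DeltaK(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)),
    defined for interior K with positive replicate sd.  Returns a table
    indexed by K with mean, sd, Lp (first difference), Lpp (second
    difference) and delta_k; the best K is the argmax of delta_k.
    """
    lnp = lnp.sort_index()
    ks = lnp.index.to_numpy()
    if len(ks) < 3:
        raise ValueError("need >= 3 consecutive K values")
    if lnp.shape[1] < 2:
        raise ValueError("need >= 2 replicates per K")
    mean = lnp.mean(axis=1)
    sd = lnp.std(axis=1, ddof=1)
    lp = mean.diff()
    lpp = mean.shift(-1) - 2 * mean + mean.shift(1)
    delta = lpp.abs() / sd
    delta[sd == 0] = np.nan
    if (sd == 0).any():
        warnings.warn("zero replicate sd at some K: delta K undefined there")
    out = pd.DataFrame({"mean_lnp": mean, "sd": sd, "Lp": lp,
                        "Lpp": lpp, "delta_k": delta})
    out.index.name = "K"
    return out


def best_k(evanno_table: pd.DataFrame) -> int:
    d = evanno_table["delta_k"].dropna()
    if d.empty:
        raise ValueError("delta K undefined for every K")
    return int(d.idxmax())


def classify_individuals(qm: QMatrix, q_threshold: float = 0.9) -> pd.DataFrame:
    """Purity flags and assigned cluster per individual.

    Pure iff max q >= threshold (inclusive); assigned cluster = argmax q,
    ties broken toward the lower cluster index and flagged.
    """
    q = qm.q
    maxq = q.max(axis=1)
    cluster = q.argmax(axis=1)          # argmax takes the first maximum: low index
    tie = (q == maxq[:, None]).sum(axis=1) > 1
    return pd.DataFrame({
        "individual": qm.individuals,
        "pop": qm.populations,
        "max_q": maxq,
        "cluster": cluster + 1,
        "pure": maxq >= q_threshold,
        "tie": tie,
    })


def population_qp(qm: QMatrix, q_threshold: float = 0.9) -> pd.Series:
    """Proportion of genetically pure individuals per population."""
    cls = classify_individuals(qm, q_threshold)
    grouped = cls.groupby("pop", sort=False)["pure"]
    sizes = grouped.size()
    if (sizes == 0).any():
        raise ValueError("empty population")
    qp = grouped.mean()
    qp.name = "Qp"
    return qp


@dataclass
class GroupPartition:
    assignment: pd.Series   # population -> group1_pure / group2_admixed / group3_pure
    qp: pd.Series
    majority_cluster: pd.Series
    qp_threshold: float

    @property
    def admixed(self) -> list[str]:
        return list(self.assignment.index[self.assignment == "group2_admixed"])


def majority_clusters(qm: QMatrix) -> pd.Series:
    """Majority cluster per population: argmax of mean q over its individuals."""
    df = pd.DataFrame(qm.q, index=pd.Index(qm.populations, name="pop"))
    mean_q = df.groupby(level="pop", sort=False).mean()
    mc = mean_q.to_numpy().argmax(axis=1) + 1
    return pd.Series(mc, index=mean_q.index, name="majority_cluster")


def partition_populations(
    qp: pd.Series,
    majority: pd.Series,
    qp_threshold: float = 0.8,
) -> GroupPartition:
    """Three-way population partition from Qp and per-population majority cluster.

    Qp < threshold -> admixed group 2; otherwise pure group 1 or 3 according
    to the majority cluster (cluster 1 -> group1, any other -> group3).
    Both thresholds are boundary-inclusive.
    """
    majority = majority.reindex(qp.index)
    if majority.isna().any():
        raise ValueError("majority cluster missing for some populations")
    labels = {}
    for pop in qp.index:
        if qp[pop] < qp_threshold:
            labels[pop] = "group2_admixed"
        else:
            labels[pop] = "group1_pure" if majority[pop] == 1 else "group3_pure"
    assignment = pd.Series(labels, name="group").loc[qp.index]
    if not (assignment == "group2_admixed").any():
        warnings.warn("admixed group is empty at this threshold")
    return GroupPartition(assignment, qp, majority, qp_threshold)
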