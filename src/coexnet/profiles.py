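"""Cluster expression profiles, gene-set enrichment and the marker ratio screen.

``cluster_profiles`` reduces each cluster to the unweighted mean TPM of its
members per sample — the standard way to read what a co-expression cluster
"does" across an atlas.  ``gene_set_enrichment`` scores the overlap of each
cluster with user-supplied gene sets (GMT format) by the one-sided
hypergeometric tail, Benjamini–Hochberg corrected across all cluster x set
pairs.  ``group_ratio_screen`` is the averaged-expression marker screen:
mean expression in group A over mean in group B with a pseudocount, e.g. to
rank genes by macrophage-vs-DC enrichment and report everything at least as
enriched as a chosen reference marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix, SampleAnnotation
from .mcl import ClusterSet


class ProfileError(ValueError):
    pass


@dataclass
class ClusterProfile:
    cluster_number: int
    n_members: int
    profile: pd.Series  # per-sample mean TPM of member genes


def cluster_profiles(cs: ClusterSet,
                     matrix: ExpressionMatrix) -> list[ClusterProfile]:
    """Per-cluster unweighted mean TPM per sample."""
    known = set(matrix.gene_ids)
    out = []
    for k, members in enumerate(cs.clusters, start=1):
        missing = [g for g in members if g not in known]
        if missing:
            raise ProfileError(
                f"cluster {k} member {missing[0]!r} absent from matrix")
        sub = matrix.data.loc[sorted(members)]
        out.append(ClusterProfile(cluster_number=k, n_members=len(members),
                                  profile=sub.mean(axis=0)))
    return out


def profiles_table(profiles: list[ClusterProfile]) -> pd.DataFrame:
    df = pd.DataFrame({f"cluster_{p.cluster_number}": p.profile
                       for p in profiles}).T
    df.insert(0, "n_members", [p.n_members for p in profiles])
    return df


def group_ratio_screen(matrix: ExpressionMatrix, annotation: SampleAnnotation,
                       group_a: str = "mononuclear", group_b: str = "DC",
                       column: str = "cell_type_class",
                       epsilon: float = 1.0,
                       reference_gene: str | None = None) -> pd.DataFrame:
    """Mean-expression ratio screen between two sample groups.

    ratio = (mean_A + eps) / (mean_B + eps); the pseudocount keeps ratios
    finite for genes silent in one group and satisfies the exact reciprocal
    identity ratio(A,B) * ratio(B,A) = 1.  With ``reference_gene`` set, a
    boolean column flags genes enriched at least as strongly as the
    reference.  Sorted by descending ratio.
    """
    annotation.check_covers(matrix)
    samples_a = [s for s in annotation.samples_where(column, group_a)
                 if s in matrix.data.columns]
    samples_b = [s for s in annotation.samples_where(column, group_b)
                 if s in matrix.data.columns]
    if not samples_a or not samples_b:
        raise ProfileError(
            f"empty group: {group_a!r} has {len(samples_a)} samples, "
            f"{group_b!r} has {len(samples_b)}")
    mean_a = matrix.data[samples_a].mean(axis=1)
    mean_b = matrix.data[samples_b].mean(axis=1)
    ratio = (mean_a + epsilon) / (mean_b + epsilon)
    df = pd.DataFrame({"mean_a": mean_a, "mean_b": mean_b, "ratio": ratio})
    if reference_gene is not None:
        if reference_gene not in df.index:
            raise ProfileError(f"reference gene {reference_gene!r} not in matrix")
        df["ge_reference"] = df["ratio"] >= df.loc[reference_gene, "ratio"]
    return df.sort_values("ratio", ascending=False, kind="stable")


def gene_set_enrichment(cs: ClusterSet, gene_sets: dict,
                        universe) -> pd.DataFrame:
    """Hypergeometric enrichment of every cluster in every gene set.

    For a universe of N genes, a set with K universe members and a cluster
    with n universe members overlapping in k genes, the p-value is the upper
    tail P(X >= k) of Hypergeometric(N, K, n).  q-values are
    Benjamini–Hochberg across all (cluster, set) pairs jointly.
    """
    universe = set(universe)
    if not universe:
        raise ProfileError("universe is empty")
    rows = []
    for k_idx, members in enumerate(cs.clusters, start=1):
        cluster_u = set(members) & universe
        for name, genes in gene_sets.items():
            set_u = set(genes) & universe
            overlap = cluster_u & set_u
            p = float(hypergeom.sf(len(overlap) - 1, len(universe),
                                   len(set_u), len(cluster_u)))
            rows.append({"cluster_number": k_idx, "gene_set": name,
                         "cluster_size": len(cluster_u),
                         "set_size": len(set_u), "overlap": len(overlap),
                         "universe_size": len(universe), "p_value": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


# -- GMT gene-set I/O ----------------------------------------------------------

def read_gmt(path) -> dict:
    """Read named gene sets from GMT: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ProfileError(f"{path}:{line_no}: GMT line needs >= 3 fields")
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(gene_sets: dict, path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            members = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")
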