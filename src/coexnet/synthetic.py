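"""Synthetic expression-atlas generator with full ground truth.

Emulates the statistical structure a correlation-network meta-analysis of a
bulk RNA-seq atlas assumes, so every downstream stage can be exercised and
validated offline:

* power-law (Zipf-like) baseline transcript abundance, ``b(rank) ∝ rank^-a``;
* planted co-expression modules whose members are jointly up-regulated
  (multiplicatively) in defined sample groups;
* low-variance housekeeping genes;
* an "immediate-early-gene" (IEG) artifact module active in a random half of
  samples irrespective of biology, mimicking dissociation-induced stress;
* contamination modules confined to the libraries of a single project/batch;
* log-normal multiplicative measurement noise;
* a count layer: per-library read totals allocated multinomially over
  length-weighted TPM proportions, plus without-replacement downsampling of
  libraries to a fixed depth (the depth-normalisation step of the analysis).

Every random draw derives from a single seed through a fixed seed-splitting
scheme (one :class:`numpy.random.SeedSequence` child per purpose, one per
module), so adding a module never perturbs the draws of earlier modules and
identical specs give bit-identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, SampleAnnotation, MatrixError, TPM_TOTAL

logger = logging.getLogger(__name__)

# spawn keys of the per-purpose random streams (stable public contract)
_STREAM_BASELINE = 0      # abundance-rank permutation
_STREAM_MEMBERSHIP = 1    # module / housekeeping gene assignment
_STREAM_NOISE = 2         # log-normal measurement noise
_STREAM_LENGTHS = 3       # transcript lengths
_STREAM_COUNTS = 4        # multinomial count allocation
_STREAM_DEPTHS = 5        # per-library sequencing depths
_STREAM_MODULE_BASE = 100  # + module index: module-specific draws (IEG sampling)


class SyntheticSpecError(ValueError):
    """Raised when a synthetic specification violates its invariants."""


@dataclass(frozen=True)
class SampleGroup:
    """A biological sample group: replicate libraries of one cell population."""

    tissue: str
    cell_type_label: str
    cell_type_class: str  # "mononuclear" | "DC"
    bioproject: str
    n_replicates: int = 4

    @property
    def group_id(self) -> str:
        return f"{self.tissue}.{self.cell_type_label}"


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module.

    kind
        ``"signal"``   — active in the listed sample groups;
        ``"ieg"``      — active in a random 50% of samples, groups ignored;
        ``"contaminant"`` — active only in libraries of ``project``.
    multiplier
        Fold-change applied to member baselines in active samples.
    """

    name: str
    n_genes: int
    kind: str = "signal"
    active_groups: tuple[str, ...] = ()
    project: str | None = None
    multiplier: float = 8.0


def default_sample_groups() -> list[SampleGroup]:
    """Eight tissue/cell-type groups x 4 replicates (6 mononuclear, 2 DC)."""
    return [
        SampleGroup("brain", "microglia", "mononuclear", "PRJX01"),
        SampleGroup("lung", "alveolar_mac", "mononuclear", "PRJX01"),
        SampleGroup("liver", "kupffer_cell", "mononuclear", "PRJX02"),
        SampleGroup("spleen", "red_pulp_mac", "mononuclear", "PRJX02"),
        SampleGroup("intestine", "intestinal_mac", "mononuclear", "PRJX03"),
        SampleGroup("blood", "monocyte", "mononuclear", "PRJX03"),
        SampleGroup("spleen", "cDC1", "DC", "PRJX04"),
        SampleGroup("lung", "cDC2", "DC", "PRJX04"),
    ]


def default_modules() -> list[ModuleSpec]:
    """Six tissue/cell-type signal modules plus IEG and contaminant artifacts."""
    return [
        ModuleSpec("microglia", 40, active_groups=("brain.microglia",)),
        ModuleSpec("alveolar", 40, active_groups=("lung.alveolar_mac",)),
        ModuleSpec("kupffer_redpulp", 40,
                   active_groups=("liver.kupffer_cell", "spleen.red_pulp_mac")),
        ModuleSpec("intestinal", 40, active_groups=("intestine.intestinal_mac",)),
        ModuleSpec("monocyte", 40, active_groups=("blood.monocyte",)),
        ModuleSpec("dendritic", 40,
                   active_groups=("spleen.cDC1", "lung.cDC2")),
        ModuleSpec("ieg", 24, kind="ieg"),
        # PRJX03 spans two groups whose signal modules are each single-group,
        # so batch-restricted contamination is distinguishable from biology
        ModuleSpec("contaminant", 16, kind="contaminant", project="PRJX03"),
    ]


@dataclass(frozen=True)
class SyntheticSpec:
    """Full specification of a synthetic expression atlas.

    Defaults define the reference study conditions used throughout the test
    suite: 2,000 genes, 8 groups x 4 replicates (32 libraries), 6 planted
    signal modules of 40 genes plus IEG and contaminant artifact modules,
    log-noise SD 0.4, Zipf exponent 1.0, 10 M reads per library downsampled
    5 times.
    """

    n_genes: int = 2000
    sample_groups: tuple[SampleGroup, ...] = field(
        default_factory=lambda: tuple(default_sample_groups()))
    modules: tuple[ModuleSpec, ...] = field(
        default_factory=lambda: tuple(default_modules()))
    zipf_exponent: float = 1.0
    noise_sigma: float = 0.4
    housekeeping_fraction: float = 0.05
    housekeeping_sigma: float = 0.1
    library_depth: int = 10_000_000
    depth_spread: float = 2.0  # library totals uniform in [depth, spread*depth]
    n_replicate_draws: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise SyntheticSpecError("n_genes must be >= 1")
        if self.zipf_exponent <= 0:
            raise SyntheticSpecError("zipf_exponent must be > 0")
        if self.noise_sigma <= 0 or self.housekeeping_sigma <= 0:
            raise SyntheticSpecError("noise sigmas must be > 0")
        if not 0 <= self.housekeeping_fraction <= 1:
            raise SyntheticSpecError("housekeeping_fraction must be in [0,1]")
        if self.library_depth < 1:
            raise SyntheticSpecError("library_depth must be >= 1")
        if self.depth_spread < 1:
            raise SyntheticSpecError("depth_spread must be >= 1")
        if not self.sample_groups:
            raise SyntheticSpecError("at least one sample group required")
        group_ids = [g.group_id for g in self.sample_groups]
        if len(set(group_ids)) != len(group_ids):
            raise SyntheticSpecError("duplicate sample group ids")
        projects = {g.bioproject for g in self.sample_groups}
        n_module_genes = sum(m.n_genes for m in self.modules)
        n_hk = int(round(self.housekeeping_fraction * self.n_genes))
        if n_module_genes + n_hk > self.n_genes:
            raise SyntheticSpecError(
                "module + housekeeping genes exceed n_genes: "
                f"{n_module_genes} + {n_hk} > {self.n_genes}")
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise SyntheticSpecError("duplicate module names")
        for m in self.modules:
            if m.n_genes < 1:
                raise SyntheticSpecError(f"module {m.name!r}: n_genes < 1")
            if m.multiplier <= 0:
                raise SyntheticSpecError(f"module {m.name!r}: multiplier <= 0")
            if m.kind == "signal":
                if not m.active_groups:
                    raise SyntheticSpecError(
                        f"signal module {m.name!r} has no active groups")
                unknown = set(m.active_groups) - set(group_ids)
                if unknown:
                    raise SyntheticSpecError(
                        f"module {m.name!r} references unknown group(s) {sorted(unknown)}")
            elif m.kind == "contaminant":
                if m.project not in projects:
                    raise SyntheticSpecError(
                        f"contaminant module {m.name!r} references unknown "
                        f"project {m.project!r}")
            elif m.kind != "ieg":
                raise SyntheticSpecError(f"unknown module kind {m.kind!r}")


@dataclass
class SyntheticTruth:
    """Ground truth for a generated atlas.

    ``membership`` covers every gene exactly once with one of
    ``module:<name>``, ``IEG``, ``contaminant:<project>``, ``housekeeping``
    or ``background``.
    """

    membership: pd.Series          # gene_id -> label
    sample_groups: pd.Series       # sample_id -> group_id
    module_active_groups: dict[str, list[str]]
    mean_matrix: pd.DataFrame      # noiseless TPM means
    gene_lengths: pd.Series        # gene_id -> effective length (nt)

    def module_gene_labels(self) -> pd.Series:
        """Labels restricted to planted-module genes (signal, IEG, contaminant)."""
        keep = ~self.membership.isin(["housekeeping", "background"])
        return self.membership[keep]

    def write(self, tsv_path, json_path=None) -> None:
        df = self.membership.rename("module_label").to_frame()
        df.index.name = "gene_id"
        df.to_csv(tsv_path, sep="\t")
        if json_path is not None:
            summary = {
                "n_genes": int(len(self.membership)),
                "labels": self.membership.value_counts().to_dict(),
                "module_active_groups": self.module_active_groups,
            }
            with open(json_path, "w") as fh:
                json.dump(summary, fh, indent=2, sort_keys=True)


def _expand_samples(spec: SyntheticSpec) -> pd.DataFrame:
    rows = []
    for g in spec.sample_groups:
        for i in range(1, g.n_replicates + 1):
            rows.append({
                "sample_id": f"{g.group_id}.r{i}",
                "tissue": g.tissue,
                "cell_type_class": g.cell_type_class,
                "cell_type_label": g.cell_type_label,
                "bioproject": g.bioproject,
                "group_id": g.group_id,
            })
    return pd.DataFrame(rows)


def generate_expression(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[ExpressionMatrix, ExpressionMatrix, SampleAnnotation, SyntheticTruth]:
    """Generate a TPM matrix, a count matrix, metadata and ground truth.

    Model: gene g receives baseline abundance ``b_g ∝ rank_g^-zipf_exponent``
    (ranks randomly permuted over genes, scaled so baselines sum to 1e6 TPM).
    In a sample where a module is active, each member's mean is multiplied by
    the module's fold-change.  Observed TPM is ``mean * exp(N(0, sigma))``
    with the housekeeping sigma for housekeeping genes, then renormalised so
    each library sums to 1e6 (proportionality within a module, and hence
    noiseless within-module correlation of 1, is preserved).  Counts allocate
    a per-library read total multinomially over length-weighted TPM shares;
    totals are uniform in ``[library_depth, depth_spread * library_depth]``
    so the downsampling stage has genuine work to do.
    """
    spec.validate()
    if seed is None:
        seed = spec.seed
    streams = {k: np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))
               for k in (_STREAM_BASELINE, _STREAM_MEMBERSHIP, _STREAM_NOISE,
                         _STREAM_LENGTHS, _STREAM_COUNTS, _STREAM_DEPTHS)}

    n = spec.n_genes
    genes = [f"g{i:05d}" for i in range(1, n + 1)]
    samples = _expand_samples(spec)
    n_samples = len(samples)

    # baseline abundance: permuted Zipf ranks scaled to TPM units
    ranks = streams[_STREAM_BASELINE].permutation(n) + 1
    base = ranks.astype(float) ** (-spec.zipf_exponent)
    base *= TPM_TOTAL / base.sum()

    # gene membership from one fixed permutation: module chunks from the
    # front, housekeeping from the back, so adding a module never perturbs
    # the membership of earlier modules or the housekeeping set
    n_hk = int(round(spec.housekeeping_fraction * n))
    perm = streams[_STREAM_MEMBERSHIP].permutation(n)
    membership = pd.Series("background", index=genes, dtype=object)
    offset = 0
    module_members: dict[str, np.ndarray] = {}
    for m in spec.modules:
        idx = perm[offset:offset + m.n_genes]
        offset += m.n_genes
        module_members[m.name] = idx
        if m.kind == "ieg":
            label = "IEG"
        elif m.kind == "contaminant":
            label = f"contaminant:{m.project}"
        else:
            label = f"module:{m.name}"
        membership.iloc[idx] = label
    hk_idx = perm[n - n_hk:] if n_hk else perm[:0]
    membership.iloc[hk_idx] = "housekeeping"

    # per-module sample activity masks
    group_of_sample = samples["group_id"].to_numpy()
    project_of_sample = samples["bioproject"].to_numpy()
    active_groups_truth: dict[str, list[str]] = {}
    mean = np.tile(base[:, None], (1, n_samples))
    for mi, m in enumerate(spec.modules):
        if m.kind == "signal":
            mask = np.isin(group_of_sample, m.active_groups)
            active_groups_truth[m.name] = list(m.active_groups)
        elif m.kind == "contaminant":
            mask = project_of_sample == m.project
            active_groups_truth[m.name] = sorted(
                set(group_of_sample[mask]))
        else:  # ieg: random half of all samples, own stream
            rng_m = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(_STREAM_MODULE_BASE + mi,)))
            k = n_samples // 2
            sel = rng_m.choice(n_samples, size=k, replace=False)
            mask = np.zeros(n_samples, dtype=bool)
            mask[sel] = True
            active_groups_truth[m.name] = sorted(
                samples.loc[mask, "sample_id"])
        rows = module_members[m.name]
        mean[np.ix_(rows, np.where(mask)[0])] *= m.multiplier

    # log-normal measurement noise, then per-library renormalisation to 1e6
    sigma = np.full(n, spec.noise_sigma)
    sigma[hk_idx] = spec.housekeeping_sigma
    noise = streams[_STREAM_NOISE].normal(0.0, 1.0, size=(n, n_samples))
    tpm = mean * np.exp(sigma[:, None] * noise)
    tpm *= TPM_TOTAL / tpm.sum(axis=0)

    # count layer: lengths log-uniform in [500, 5000] nt; reads multinomial
    # over length-weighted TPM shares at a per-library total
    lengths = np.exp(streams[_STREAM_LENGTHS].uniform(
        np.log(500.0), np.log(5000.0), size=n))
    depth_rng = streams[_STREAM_DEPTHS]
    if spec.depth_spread > 1:
        depths = depth_rng.integers(
            spec.library_depth,
            int(spec.depth_spread * spec.library_depth) + 1,
            size=n_samples)
    else:
        depths = np.full(n_samples, spec.library_depth, dtype=np.int64)
    shares = tpm * lengths[:, None]
    shares /= shares.sum(axis=0)
    counts_rng = streams[_STREAM_COUNTS]
    counts = np.empty((n, n_samples), dtype=np.int64)
    for j in range(n_samples):
        counts[:, j] = counts_rng.multinomial(int(depths[j]), shares[:, j])

    sample_ids = list(samples["sample_id"])
    tpm_matrix = ExpressionMatrix(
        pd.DataFrame(tpm, index=genes, columns=sample_ids), unit="TPM")
    count_matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=sample_ids), unit="counts")
    annotation = SampleAnnotation(
        samples[["sample_id", "tissue", "cell_type_class",
                 "cell_type_label", "bioproject"]].copy())
    truth = SyntheticTruth(
        membership=membership,
        sample_groups=pd.Series(group_of_sample, index=sample_ids),
        module_active_groups=active_groups_truth,
        mean_matrix=pd.DataFrame(mean, index=genes, columns=sample_ids),
        gene_lengths=pd.Series(lengths, index=genes),
    )
    logger.info("generated %d genes x %d samples (seed=%d)", n, n_samples, seed)
    return tpm_matrix, count_matrix, annotation, truth


def generate_replicate_draws(
    counts: ExpressionMatrix,
    depth: int,
    k: int,
    seed: int,
    with_replacement: bool = False,
) -> list[ExpressionMatrix]:
    """Downsample every library to exactly ``depth`` reads, ``k`` times.

    Default sampling is without replacement (multivariate hypergeometric per
    library), the exact model of drawing a subset of physical reads; a
    with-replacement multinomial mode is available for speed.  Column sums of
    every draw equal ``depth`` exactly.
    """
    if counts.unit != "counts":
        raise MatrixError("generate_replicate_draws expects count units")
    if depth < 1:
        raise SyntheticSpecError("depth must be >= 1")
    vals = np.rint(counts.values).astype(np.int64)
    totals = vals.sum(axis=0)
    for sample, total in zip(counts.sample_ids, totals):
        if total < depth:
            raise SyntheticSpecError(
                f"library {sample!r} has only {total} reads; cannot "
                f"downsample to {depth}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draws = []
    for _ in range(k):
        out = np.empty_like(vals)
        for j in range(vals.shape[1]):
            col = vals[:, j]
            if totals[j] == depth:
                out[:, j] = col  # exhaustive sample: the library itself
            elif with_replacement:
                p = col / totals[j]
                out[:, j] = rng.multinomial(depth, p)
            else:
                out[:, j] = rng.multivariate_hypergeometric(col, depth)
        draws.append(ExpressionMatrix(
            pd.DataFrame(out, index=counts.data.index,
                         columns=counts.data.columns),
            unit="counts"))
    return draws


# -- plain-text spec serialisation ---------------------------------------------

def spec_to_dict(spec: SyntheticSpec) -> dict:
    d = asdict(spec)
    d["sample_groups"] = [asdict(g) for g in spec.sample_groups]
    d["modules"] = [asdict(m) for m in spec.modules]
    return d


def spec_from_dict(d: dict) -> SyntheticSpec:
    d = dict(d)
    if "sample_groups" in d:
        d["sample_groups"] = tuple(
            SampleGroup(**g) for g in d["sample_groups"])
    if "modules" in d:
        d["modules"] = tuple(
            ModuleSpec(**{**m, "active_groups": tuple(m.get("active_groups", ()))})
            for m in d["modules"])
    spec = SyntheticSpec(**d)
    spec.validate()
    return spec
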