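"""Synthetic multi-batch, multi-cohort RNA-seq count studies.

Generates gene-by-sample negative-binomial count matrices with the
statistical structure the downstream analysis assumes: planted
differentially expressed marker genes, per-batch location/scale effects on
the log scale, per-sample library-size variation, subject-level biological
variation shared by replicate samples, and an immunoglobulin-like gene
class in which markers can be enriched.

The count model for gene g in sample s of subject j (group k, batch b) is

    counts_{gs} ~ NB(mean = d_s * exp(a_g + ln(2)*L_g*1[k affected]
                                      + gamma_{bg} + delta_{bg} * e_{gj}),
                     dispersion = alpha)

with variance mu + alpha*mu^2, where a_g is the gene's baseline natural-log
mean, L_g its planted log2 fold-change (0 for non-markers), gamma_{bg} an
additive per-gene batch location offset, delta_{bg} a multiplicative batch
scale factor acting on the subject-level log residual e_{gj} ~ N(0,
biological_sigma), and d_s a log-normal per-sample depth factor.  This is
exactly the additive-location / multiplicative-scale model that the
empirical-Bayes batch correction assumes, so the correction is testable by
parameter recovery.

Ground-truth columns (``is_planted_marker``, ``true_log2fc``) are emitted
only in the gene annotation written by this module and are never consumed
by any analysis module.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BatchSpec",
    "SimulationConfig",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "cohort1_config",
    "cohort2_config",
    "two_group_config",
]

METADATA_COLUMNS = [
    "sample_id",
    "subject_id",
    "batch",
    "cohort",
    "diagnosis",
    "response",
    "replicate_index",
]

ANNOTATION_COLUMNS = [
    "gene_id",
    "symbol",
    "is_immunoglobulin",
    "is_planted_marker",
    "true_log2fc",
]

#: group labels whose diagnosis is bipolar disorder
_BD_GROUPS = frozenset({"LR", "NR"})


class ConfigError(ValueError):
    """A simulation configuration violates an invariant (names the field)."""


class FormatError(ValueError):
    """A cohort file triple is inconsistent (names the offending label)."""


@dataclass
class BatchSpec:
    """One sequencing batch: its cohort, effect sizes, and sample allocation.

    ``sample_allocation`` maps group label -> number of subjects processed
    in this batch.  ``duplicate_allocation`` optionally fixes, per group,
    how many of those subjects contribute two RNA samples; when None the
    global ``replicate_probability`` of the parent config applies.
    """

    batch_id: str
    cohort_id: str
    location_shift_sigma: float = 0.0
    scale_factor_range: tuple[float, float] = (1.0, 1.0)
    sample_allocation: dict[str, int] = field(default_factory=dict)
    duplicate_allocation: dict[str, int] | None = None


@dataclass
class SimulationConfig:
    """Full description of a simulated study.

    Defaults give a desk-scale panel of 2,000 genes; the ~22,000-gene scale
    of a real LCL study is available by raising ``n_genes``.
    """

    n_genes: int = 2000
    n_marker_genes: int = 20
    marker_log2fc_range: tuple[float, float] = (1.0, 3.0)
    ig_gene_fraction: float = 0.012
    ig_marker_enrichment: float = 25.0
    baseline_mean_log_range: tuple[float, float] = (1.0, 7.0)
    dispersion: float = 0.1
    group_sizes: dict[str, int] = field(default_factory=lambda: {"LR": 10, "NR": 10})
    replicate_probability: float = 0.0
    batches: list[BatchSpec] = field(default_factory=list)
    library_size_sigma: float = 0.15
    biological_sigma: float = 0.3
    affected_groups: tuple[str, ...] | None = None
    marker_sign_probability: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.batches:
            # single batch holding every subject
            self.batches = [
                BatchSpec(
                    batch_id="b1",
                    cohort_id="c1",
                    sample_allocation=dict(self.group_sizes),
                )
            ]

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if not 0 <= self.n_marker_genes <= self.n_genes:
            raise ConfigError("n_marker_genes must be in [0, n_genes]")
        for name in ("ig_gene_fraction", "replicate_probability",
                     "marker_sign_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.ig_marker_enrichment < 0:
            raise ConfigError("ig_marker_enrichment must be >= 0")
        lo, hi = self.marker_log2fc_range
        if not 0 <= lo <= hi:
            raise ConfigError("marker_log2fc_range must satisfy 0 <= lo <= hi")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.library_size_sigma < 0:
            raise ConfigError("library_size_sigma must be >= 0")
        if self.biological_sigma < 0:
            raise ConfigError("biological_sigma must be >= 0")
        if not self.group_sizes:
            raise ConfigError("group_sizes must be non-empty")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ConfigError(f"group_sizes[{g!r}] must be >= 1")
        if self.affected_groups is not None:
            unknown = set(self.affected_groups) - set(self.group_sizes)
            if unknown:
                raise ConfigError(f"affected_groups contains unknown groups {sorted(unknown)}")
        known = {"CTRL"} | _BD_GROUPS
        unknown = set(self.group_sizes) - known
        if unknown:
            raise ConfigError(
                f"group_sizes contains unrecognized group labels {sorted(unknown)}; "
                f"expected a subset of {sorted(known)}"
            )
        # batch allocations must tile the groups exactly
        alloc: dict[str, int] = {g: 0 for g in self.group_sizes}
        for b in self.batches:
            lo, hi = b.scale_factor_range
            if not 0 < lo <= hi:
                raise ConfigError(
                    f"batches[{b.batch_id!r}].scale_factor_range bounds must be > 0"
                )
            if b.location_shift_sigma < 0:
                raise ConfigError(
                    f"batches[{b.batch_id!r}].location_shift_sigma must be >= 0"
                )
            for g, n in b.sample_allocation.items():
                if g not in alloc:
                    raise ConfigError(
                        f"batches[{b.batch_id!r}].sample_allocation has unknown group {g!r}"
                    )
                alloc[g] += n
            if b.duplicate_allocation is not None:
                for g, n in b.duplicate_allocation.items():
                    if n > b.sample_allocation.get(g, 0):
                        raise ConfigError(
                            f"batches[{b.batch_id!r}].duplicate_allocation[{g!r}] "
                            "exceeds its sample_allocation"
                        )
        if alloc != dict(self.group_sizes):
            raise ConfigError(
                f"batch sample_allocation totals {alloc} do not match group_sizes "
                f"{dict(self.group_sizes)}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        batches = [BatchSpec(**b) if isinstance(b, dict) else b for b in d.pop("batches", [])]
        for key in ("marker_log2fc_range", "baseline_mean_log_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("affected_groups") is not None:
            d["affected_groups"] = tuple(d["affected_groups"])
        cfg = cls(batches=batches, **d)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _affected_groups(config: SimulationConfig) -> frozenset[str]:
    if config.affected_groups is not None:
        return frozenset(config.affected_groups)
    groups = sorted(config.group_sizes)
    return frozenset(groups[1:])


def _gene_truth(config: SimulationConfig, rng: np.random.Generator) -> dict:
    """Draw the gene-level ground truth (baselines, markers, Ig flags)."""
    G = config.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(G)])
    a = rng.uniform(*config.baseline_mean_log_range, size=G)  # natural-log baseline
    marker_idx = rng.choice(G, size=config.n_marker_genes, replace=False)
    is_marker = np.zeros(G, dtype=bool)
    is_marker[marker_idx] = True
    log2fc = np.zeros(G)
    if config.n_marker_genes:
        mag = rng.uniform(*config.marker_log2fc_range, size=config.n_marker_genes)
        sign = np.where(
            rng.random(config.n_marker_genes) < config.marker_sign_probability, 1.0, -1.0
        )
        log2fc[marker_idx] = mag * sign
    p_ig_marker = min(1.0, config.ig_gene_fraction * config.ig_marker_enrichment)
    is_ig = np.where(
        is_marker,
        rng.random(G) < p_ig_marker,
        rng.random(G) < config.ig_gene_fraction,
    )
    symbols = np.where(
        is_ig,
        np.char.add("IGHV", gene_ids.astype(str)),
        np.char.add("SYM", gene_ids.astype(str)),
    )
    return {
        "gene_ids": gene_ids,
        "baseline_log_mean": a,
        "is_marker": is_marker,
        "log2fc": log2fc,
        "is_ig": is_ig,
        "symbols": symbols,
    }


def generate_cohort(
    config: SimulationConfig,
    gene_truth: dict | None = None,
    return_params: bool = False,
):
    """Simulate a count study.

    Returns ``(counts, metadata, annotation)`` where ``counts`` is a
    genes x samples integer DataFrame (index ``gene_id``), ``metadata`` has
    one row per sample and ``annotation`` one row per gene including the
    simulation ground truth.  Deterministic given ``config.seed``.

    ``gene_truth`` (from a previous cohort's generation) fixes the
    gene-level ground truth so a second cohort shares the same planted
    markers; see :func:`generate_cohort_pair`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes

    truth = _gene_truth(config, rng) if gene_truth is None else gene_truth
    if len(truth["gene_ids"]) != G:
        raise ConfigError("gene_truth does not match n_genes")
    gene_ids = truth["gene_ids"]
    a = truth["baseline_log_mean"]
    is_marker = truth["is_marker"]
    log2fc = truth["log2fc"]
    is_ig = truth["is_ig"]
    symbols = truth["symbols"]

    # ---- subjects and samples ----
    affected = _affected_groups(config)
    meta_rows: list[dict] = []
    sample_batch: list[BatchSpec] = []
    sample_subject_index: list[int] = []
    subject_group: list[str] = []
    subj_counter = 0
    for b in config.batches:
        for group in sorted(b.sample_allocation):
            n_subj = b.sample_allocation[group]
            if b.duplicate_allocation is not None:
                n_dup = b.duplicate_allocation.get(group, 0)
                dup_flags = np.array([True] * n_dup + [False] * (n_subj - n_dup))
            else:
                dup_flags = rng.random(n_subj) < config.replicate_probability
            for j in range(n_subj):
                # cohort-qualified so joint multi-cohort frames never collide
                sid = f"{b.cohort_id}-S{subj_counter:03d}"
                subject_group.append(group)
                n_rep = 2 if dup_flags[j] else 1
                for r in range(n_rep):
                    meta_rows.append(
                        {
                            "sample_id": f"{sid}_r{r}",
                            "subject_id": sid,
                            "batch": b.batch_id,
                            "cohort": b.cohort_id,
                            "diagnosis": "CTRL" if group == "CTRL" else "BD",
                            "response": "NA" if group == "CTRL" else group,
                            "replicate_index": r,
                        }
                    )
                    sample_batch.append(b)
                    sample_subject_index.append(subj_counter)
                subj_counter += 1
    metadata = pd.DataFrame(meta_rows, columns=METADATA_COLUMNS)
    n_subjects = subj_counter
    S = len(metadata)

    # ---- batch parameters (per gene) ----
    batch_gamma: dict[str, np.ndarray] = {}
    batch_delta: dict[str, np.ndarray] = {}
    for b in config.batches:
        batch_gamma[b.batch_id] = (
            rng.normal(0.0, b.location_shift_sigma, size=G)
            if b.location_shift_sigma > 0
            else np.zeros(G)
        )
        batch_delta[b.batch_id] = rng.uniform(*b.scale_factor_range, size=G)

    # ---- subject-level biological residuals ----
    e = (
        rng.normal(0.0, config.biological_sigma, size=(G, n_subjects))
        if config.biological_sigma > 0
        else np.zeros((G, n_subjects))
    )

    # ---- per-sample depth ----
    depth = (
        rng.lognormal(0.0, config.library_size_sigma, size=S)
        if config.library_size_sigma > 0
        else np.ones(S)
    )

    # ---- assemble means and draw counts ----
    group_arr = np.array(subject_group)
    effect = np.zeros((G, n_subjects))
    if affected:
        hit = np.isin(group_arr, sorted(affected))
        effect[:, hit] = (np.log(2.0) * log2fc)[:, None]
    log_mu_subj = a[:, None] + effect  # (G, n_subjects), before batch & residual

    counts = np.empty((G, S), dtype=np.int64)
    alpha = config.dispersion
    for s in range(S):
        j = sample_subject_index[s]
        b = sample_batch[s]
        log_mu = (
            log_mu_subj[:, j]
            + batch_gamma[b.batch_id]
            + batch_delta[b.batch_id] * e[:, j]
        )
        mu = depth[s] * np.exp(log_mu)
        if alpha == 0:
            counts[:, s] = rng.poisson(mu)
        else:
            n_nb = 1.0 / alpha
            p_nb = n_nb / (n_nb + mu)
            counts[:, s] = rng.negative_binomial(n_nb, p_nb)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=metadata["sample_id"].to_numpy())
    annotation = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": symbols,
            "is_immunoglobulin": is_ig,
            "is_planted_marker": is_marker,
            "true_log2fc": log2fc,
        },
        columns=ANNOTATION_COLUMNS,
    )
    if return_params:
        params = {
            "batch_gamma": batch_gamma,   # per-gene additive log offsets
            "batch_delta": batch_delta,   # per-gene residual scale factors
            "depth": pd.Series(depth, index=metadata["sample_id"].to_numpy()),
        }
        return counts_df, metadata, annotation, params
    return counts_df, metadata, annotation


def generate_cohort_pair(
    config1: SimulationConfig, config2: SimulationConfig
) -> tuple[tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame],
           tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]]:
    """Two cohorts sharing one gene-level ground truth (same planted
    markers and baselines) but independent subjects, batches and noise.

    The truth is drawn from ``config1.seed``; ``config2`` should carry a
    different seed so its sampling noise is independent.
    """
    for f in ("n_genes", "n_marker_genes", "marker_log2fc_range",
              "ig_gene_fraction", "ig_marker_enrichment"):
        if getattr(config1, f) != getattr(config2, f):
            raise ConfigError(f"paired cohorts must agree on {f}")
    config1.validate()
    if config2.seed == config1.seed:  # keep the noise streams independent
        config2 = dataclasses.replace(config2, seed=config1.seed + 1)
    truth = _gene_truth(config1, np.random.default_rng(config1.seed))
    return (
        generate_cohort(config1, gene_truth=truth),
        generate_cohort(config2, gene_truth=truth),
    )


# ---------------------------------------------------------------------------
# presets


def cohort1_config(seed: int = 0, n_genes: int = 2000, **overrides) -> SimulationConfig:
    """Three-batch discovery cohort: 10 CTRL / 9 LR / 10 NR subjects,
    46 RNA samples in total (duplicates for some subjects)."""
    batches = [
        BatchSpec(
            batch_id="batch1", cohort_id="cohort1",
            location_shift_sigma=0.6, scale_factor_range=(0.8, 1.25),
            sample_allocation={"LR": 5, "NR": 4, "CTRL": 3},
            duplicate_allocation={"LR": 5, "NR": 4, "CTRL": 3},
        ),
        BatchSpec(
            batch_id="batch2", cohort_id="cohort1",
            location_shift_sigma=0.6, scale_factor_range=(0.8, 1.25),
            sample_allocation={"LR": 1, "NR": 2, "CTRL": 3},
            duplicate_allocation={"LR": 1, "NR": 2, "CTRL": 1},
        ),
        BatchSpec(
            batch_id="batch3", cohort_id="cohort1",
            location_shift_sigma=0.6, scale_factor_range=(0.8, 1.25),
            sample_allocation={"LR": 3, "NR": 4, "CTRL": 4},
            duplicate_allocation={"LR": 0, "NR": 1, "CTRL": 0},
        ),
    ]
    kwargs = dict(
        n_genes=n_genes,
        n_marker_genes=20,
        marker_log2fc_range=(1.5, 3.0),
        group_sizes={"LR": 9, "NR": 10, "CTRL": 10},
        affected_groups=("NR",),
        batches=batches,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def cohort2_config(seed: int = 0, n_genes: int = 2000, **overrides) -> SimulationConfig:
    """Single-batch replication cohort: 12 LR / 12 NR, no replicates.

    The batch effect is much stronger than the within-lab batches of
    :func:`cohort1_config`: cross-laboratory protocol differences (library
    prep, chemistry) shift individual genes by orders of magnitude, so the
    per-gene location sd is set comparable to the planted marker effects —
    large enough that an uncorrected predictor genuinely fails on the
    second cohort.
    """
    batches = [
        BatchSpec(
            batch_id="batch4", cohort_id="cohort2",
            location_shift_sigma=3.0, scale_factor_range=(0.4, 2.5),
            sample_allocation={"LR": 12, "NR": 12},
        )
    ]
    kwargs = dict(
        n_genes=n_genes,
        n_marker_genes=20,
        marker_log2fc_range=(1.5, 3.0),
        group_sizes={"LR": 12, "NR": 12},
        affected_groups=("NR",),
        batches=batches,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def two_group_config(
    seed: int = 0,
    n_per_group: int = 20,
    n_genes: int = 2000,
    n_batches: int = 3,
    groups: tuple[str, str] = ("LR", "NR"),
    location_shift_sigma: float = 0.6,
    **overrides,
) -> SimulationConfig:
    """Balanced two-group study spread over ``n_batches`` batches."""
    g1, g2 = groups
    batches = []
    base, extra = divmod(n_per_group, n_batches)
    for i in range(n_batches):
        n_i = base + (1 if i < extra else 0)
        batches.append(
            BatchSpec(
                batch_id=f"b{i + 1}", cohort_id="c1",
                location_shift_sigma=location_shift_sigma,
                scale_factor_range=(0.8, 1.25),
                sample_allocation={g1: n_i, g2: n_i},
            )
        )
    kwargs = dict(
        n_genes=n_genes,
        n_marker_genes=20,
        marker_log2fc_range=(1.5, 3.0),
        group_sizes={g1: n_per_group, g2: n_per_group},
        affected_groups=(g2,),
        batches=batches,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


# ---------------------------------------------------------------------------
# I/O


def write_cohort(
    prefix: str | Path,
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    annotation: pd.DataFrame,
) -> dict[str, Path]:
    """Write the triple as ``<prefix>.counts.tsv`` / ``.metadata.csv`` /
    ``.annotation.csv``; returns the paths."""
    _check_triple(counts, metadata, annotation)
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": prefix.with_suffix(".counts.tsv"),
        "metadata": prefix.with_suffix(".metadata.csv"),
        "annotation": prefix.with_suffix(".annotation.csv"),
    }
    counts.to_csv(paths["counts"], sep="\t")
    metadata.to_csv(paths["metadata"], index=False)
    annotation.to_csv(paths["annotation"], index=False)
    return paths


def read_cohort(prefix: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read the triple written by :func:`write_cohort`; validates consistency."""
    prefix = Path(prefix)
    counts = pd.read_csv(prefix.with_suffix(".counts.tsv"), sep="\t", index_col="gene_id")
    metadata = pd.read_csv(prefix.with_suffix(".metadata.csv"), dtype={"replicate_index": int})
    annotation = pd.read_csv(prefix.with_suffix(".annotation.csv"))
    metadata["response"] = metadata["response"].fillna("NA")
    _check_triple(counts, metadata, annotation)
    return counts, metadata, annotation


def _check_triple(
    counts: pd.DataFrame, metadata: pd.DataFrame, annotation: pd.DataFrame
) -> None:
    dup = counts.index[counts.index.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate gene_id {dup[0]!r} in counts")
    dup = counts.columns[counts.columns.duplicated()]
    if len(dup):
        raise FormatError(f"duplicate sample_id {dup[0]!r} in counts")
    if (counts.to_numpy() < 0).any():
        raise FormatError("negative count encountered")
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise FormatError(f"metadata missing column {missing[0]!r}")
    meta_ids = set(metadata["sample_id"])
    if len(meta_ids) != len(metadata):
        raise FormatError("duplicate sample_id in metadata")
    extra = set(counts.columns) - meta_ids
    if extra:
        raise FormatError(f"sample {sorted(extra)[0]!r} in counts missing from metadata")
    extra = meta_ids - set(counts.columns)
    if extra:
        raise FormatError(f"sample {sorted(extra)[0]!r} in metadata missing from counts")
    bad = metadata[
        (metadata["diagnosis"] == "CTRL") != (metadata["response"] == "NA")
    ]
    if len(bad):
        raise FormatError(
            f"sample {bad['sample_id'].iloc[0]!r}: response must be NA iff diagnosis is CTRL"
        )
    ann_ids = set(annotation["gene_id"])
    extra = set(counts.index) - ann_ids
    if extra:
        raise FormatError(f"gene {sorted(extra)[0]!r} in counts missing from annotation")
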