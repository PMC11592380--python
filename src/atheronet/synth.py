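"""Synthetic data with planted ground truth.

Every downstream stage of the pipeline (differential expression, weighted
co-expression modules, geneset overlap, PPI subnetworks, feed-forward loops)
is exercised on data generated here, so each generator records exactly what
it planted:

* **Expression**: a two-group gene x sample matrix on the log2 scale.
  Co-expression modules follow a single-latent-factor model with equal
  loadings — gene ``g`` in module ``m`` is ``loading * f_m + N(0, noise_sd^2)``
  with ``f_m ~ N(0, 1)`` per sample — which gives a closed-form within-module
  correlation ``loading^2 / (loading^2 + noise_sd^2)``.  Differential
  expression is an additive case-group shift of ``±de_log2fc``, so the
  estimand of a two-group mean difference is exact.  Batch effects are
  additive per-(gene, batch) Gaussian offsets.
* **Regulatory interactions**: three edge tables (miRNA->mRNA, TF->mRNA,
  miRNA<->TF) containing a set of planted closed 3-node feed-forward-loop
  triangles plus optional random decoy edges.  Decoys are rejection-sampled
  so they never close an unplanted triangle unless explicitly allowed.
* **Geneset library**: one set enriched for a target gene list plus random
  background sets, GMT-serializable.

All generators are pure functions of their :class:`SynthConfig` (including
the seed): identical configs reproduce identical outputs bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CASE, CONTROL, ExpressionDataset


class ConfigError(ValueError):
    """A SynthConfig field is out of range or infeasible."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults emulate a small two-arm microarray cohort: 2,000 genes,
    30 samples per arm in 2 scanning batches, 10% of genes differentially
    expressed at |log2FC| = 1 over unit-variance noise, and five planted
    co-expression modules of 40 genes at within-module correlation 0.8.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 30
    n_batches: int = 2
    frac_de: float = 0.1
    de_log2fc: float = 1.0
    n_modules: int = 5
    module_size: int = 40
    module_cor: float = 0.8
    noise_sd: float = 1.0
    batch_sd: float = 0.0
    n_tfs: int = 10
    n_mirnas: int = 10
    n_planted_ffls: int = 10
    edge_noise_frac: float = 0.0
    de_in_modules: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_samples_per_group", "n_batches"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("n_modules", "module_size", "n_tfs", "n_mirnas",
                     "n_planted_ffls"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("frac_de", "edge_noise_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_modules and not 0.0 < self.module_cor < 1.0:
            raise ConfigError(f"module_cor must be in (0, 1), got {self.module_cor}")
        if self.n_modules * self.module_size > self.n_genes:
            raise ConfigError(
                "n_modules * module_size exceeds n_genes "
                f"({self.n_modules} * {self.module_size} > {self.n_genes})"
            )
        if self.noise_sd < 0 or self.batch_sd < 0:
            raise ConfigError("noise_sd and batch_sd must be >= 0")
        if self.n_planted_ffls > self.n_tfs * self.n_mirnas:
            raise ConfigError(
                "n_planted_ffls exceeds the number of distinct (TF, miRNA) "
                f"pairs ({self.n_tfs} * {self.n_mirnas})"
            )


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators."""

    de_log2fc: dict[str, float] = field(default_factory=dict)
    module_of: dict[str, str] = field(default_factory=dict)
    batch_offset: dict[tuple[str, str], float] = field(default_factory=dict)
    planted_ffls: set[tuple[str, str, str]] = field(default_factory=set)

    @property
    def de_genes(self) -> set[str]:
        return set(self.de_log2fc)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_log2fc": self.de_log2fc,
            "module_of": self.module_of,
            "batch_offset": {f"{g}\t{b}": v for (g, b), v in self.batch_offset.items()},
            "planted_ffls": sorted(list(t) for t in self.planted_ffls),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def tf_ids(n: int) -> list[str]:
    return [f"TF{i:03d}" for i in range(1, n + 1)]


def mirna_ids(n: int) -> list[str]:
    return [f"miR-{i:03d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def gen_expression(cfg: SynthConfig) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Generate a two-group expression matrix with planted DE genes,
    latent-factor modules, and additive batch offsets."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    genes = gene_ids(cfg.n_genes)
    n = cfg.n_samples_per_group
    samples = [f"S{i:04d}" for i in range(1, 2 * n + 1)]
    groups = pd.Series([CASE] * n + [CONTROL] * n, index=samples)
    # round-robin batches so group and batch are not confounded
    batch_labels = [f"B{(i % cfg.n_batches) + 1}" for i in range(2 * n)]
    batches = pd.Series(batch_labels, index=samples)

    mat = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, 2 * n))
    truth = SyntheticTruth()

    # modules: leading genes, single latent factor per module, equal loadings
    truth.module_of = {g: "none" for g in genes}
    if cfg.n_modules:
        c = cfg.module_cor
        loading = 1.0 if cfg.noise_sd == 0 else cfg.noise_sd * np.sqrt(c / (1.0 - c))
        for m in range(cfg.n_modules):
            factor = rng.normal(0.0, 1.0, size=2 * n)
            lo, hi = m * cfg.module_size, (m + 1) * cfg.module_size
            mat[lo:hi, :] += loading * factor
            for g in genes[lo:hi]:
                truth.module_of[g] = f"M{m + 1}"

    # planted DE: random subset, alternating signs, additive case-group shift.
    # With de_in_modules, module genes are made DE first so that the module
    # structure survives a downstream DEG screen.
    n_de = int(round(cfg.frac_de * cfg.n_genes))
    n_module_genes = cfg.n_modules * cfg.module_size
    if cfg.de_in_modules and n_module_genes:
        head = np.arange(min(n_de, n_module_genes))
        n_rest = n_de - head.size
        rest = (
            n_module_genes
            + rng.choice(cfg.n_genes - n_module_genes, size=n_rest, replace=False)
            if n_rest
            else np.empty(0, dtype=int)
        )
        de_idx = np.sort(np.concatenate([head, rest]).astype(int))
    else:
        de_idx = np.sort(rng.choice(cfg.n_genes, size=n_de, replace=False))
    case_mask = (groups == CASE).to_numpy()
    for rank, gi in enumerate(de_idx):
        # module genes move together (sign per module); the rest alternate
        if cfg.de_in_modules and gi < n_module_genes:
            sign = 1.0 if (gi // cfg.module_size) % 2 == 0 else -1.0
        else:
            sign = 1.0 if rank % 2 == 0 else -1.0
        mat[gi, case_mask] += sign * cfg.de_log2fc
        truth.de_log2fc[genes[gi]] = sign * cfg.de_log2fc

    # batch offsets per (gene, batch)
    if cfg.batch_sd > 0:
        uniq = sorted(set(batch_labels))
        offsets = rng.normal(0.0, cfg.batch_sd, size=(cfg.n_genes, len(uniq)))
        for bj, b in enumerate(uniq):
            cols = (batches == b).to_numpy()
            mat[:, cols] += offsets[:, [bj]]
            for gi, g in enumerate(genes):
                truth.batch_offset[(g, b)] = float(offsets[gi, bj])

    values = pd.DataFrame(mat, index=genes, columns=samples)
    return ExpressionDataset(values=values, groups=groups, batches=batches), truth


# ---------------------------------------------------------------------------
# regulatory interactions
# ---------------------------------------------------------------------------

#: direction tags for miRNA-TF edges
MIRNA_REPRESSES_TF = "mirna_represses_tf"
TF_REGULATES_MIRNA = "tf_regulates_mirna"


@dataclass
class InteractionTables:
    """The three regulatory edge sets feeding feed-forward-loop construction."""

    mirna_mrna: set[tuple[str, str]] = field(default_factory=set)
    tf_mrna: set[tuple[str, str]] = field(default_factory=set)
    mirna_tf: set[tuple[str, str, str]] = field(default_factory=set)  # (m, t, direction)

    def mirna_tf_pairs(self) -> set[tuple[str, str]]:
        return {(m, t) for m, t, _ in self.mirna_tf}

    def n_edges(self) -> int:
        return len(self.mirna_mrna) + len(self.tf_mrna) + len(self.mirna_tf_pairs())


def _all_triangles(tables: "InteractionTables") -> set[tuple[str, str, str]]:
    """All closed (tf, mirna, mrna) triangles in the tables."""
    tf_of: dict[str, set[str]] = {}
    for t, g in tables.tf_mrna:
        tf_of.setdefault(g, set()).add(t)
    mt = tables.mirna_tf_pairs()
    out = set()
    for m, g in tables.mirna_mrna:
        for t in tf_of.get(g, ()):  # noqa: E501
            if (m, t) in mt:
                out.add((t, m, g))
    return out


def _closes_new_triangle(
    tables: InteractionTables,
    candidate: tuple[str, ...],
    kind: str,
    planted: set[tuple[str, str, str]],
) -> bool:
    """Would adding `candidate` to table `kind` close a non-planted FFL triangle?"""
    mm = set(tables.mirna_mrna)
    tm = set(tables.tf_mrna)
    mt = tables.mirna_tf_pairs()
    if kind == "mirna_mrna":
        mm.add(candidate)
    elif kind == "tf_mrna":
        tm.add(candidate)
    else:
        mt.add(candidate[:2])
    tf_of: dict[str, set[str]] = {}
    for t, g in tm:
        tf_of.setdefault(g, set()).add(t)
    for m, g in mm:
        for t in tf_of.get(g, ()):  # triangle (t, m, g) iff (m, t) regulatory edge
            if (m, t) in mt and (t, m, g) not in planted:
                return True
    return False


def gen_interactions(
    cfg: SynthConfig,
    mrna_pool: list[str] | None = None,
    allow_decoy_triangles: bool = False,
) -> tuple[InteractionTables, SyntheticTruth]:
    """Generate regulatory tables with ``cfg.n_planted_ffls`` closed triangles.

    Each planted triple (t, m, g) contributes edges m->g, t->g and an
    m<->t edge whose regulatory direction is drawn at random (so the three
    loop types all occur).  Decoy edges are added per table at
    ``edge_noise_frac`` of the planted edge count and, unless
    ``allow_decoy_triangles``, rejection-sampled against closing any
    unplanted triangle.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 2])
    tfs = tf_ids(cfg.n_tfs)
    mirs = mirna_ids(cfg.n_mirnas)
    pool = list(mrna_pool) if mrna_pool is not None else gene_ids(cfg.n_genes)
    if cfg.n_planted_ffls and not pool:
        raise ConfigError("mRNA pool is empty but n_planted_ffls > 0")

    tables = InteractionTables()
    truth = SyntheticTruth()

    if cfg.n_planted_ffls:
        pair_idx = rng.choice(
            cfg.n_tfs * cfg.n_mirnas, size=cfg.n_planted_ffls, replace=False
        )
        for k in np.sort(pair_idx):
            t = tfs[k // cfg.n_mirnas]
            m = mirs[k % cfg.n_mirnas]
            direction = MIRNA_REPRESSES_TF if rng.random() < 0.5 else TF_REGULATES_MIRNA
            # resample the target so planted edges never combine into an
            # accidental unplanted triangle (keeps noiseless recovery exact)
            placed = False
            for _ in range(200):
                g = pool[int(rng.integers(len(pool)))]
                trial = InteractionTables(
                    mirna_mrna=tables.mirna_mrna | {(m, g)},
                    tf_mrna=tables.tf_mrna | {(t, g)},
                    mirna_tf=tables.mirna_tf | {(m, t, direction)},
                )
                triple = (t, m, g)
                if _all_triangles(trial) <= truth.planted_ffls | {triple}:
                    tables = trial
                    truth.planted_ffls.add(triple)
                    placed = True
                    break
            if not placed:
                raise ConfigError(
                    "could not place all planted FFLs without accidental "
                    "triangles; reduce n_planted_ffls or enlarge the mRNA pool"
                )

    # decoy edges
    n_decoy = int(round(cfg.edge_noise_frac * max(1, cfg.n_planted_ffls)))
    if cfg.edge_noise_frac > 0:
        specs = [
            ("mirna_mrna", mirs, pool),
            ("tf_mrna", tfs, pool),
            ("mirna_tf", mirs, tfs),
        ]
        for kind, src, dst in specs:
            added, attempts = 0, 0
            while added < n_decoy and attempts < 200 * max(1, n_decoy):
                attempts += 1
                a = src[int(rng.integers(len(src)))]
                b = dst[int(rng.integers(len(dst)))]
                if kind == "mirna_tf":
                    direction = (
                        MIRNA_REPRESSES_TF if rng.random() < 0.5 else TF_REGULATES_MIRNA
                    )
                    cand: tuple[str, ...] = (a, b, direction)
                    present = (a, b) in tables.mirna_tf_pairs()
                else:
                    cand = (a, b)
                    present = cand in getattr(tables, kind)
                if present:
                    continue
                if not allow_decoy_triangles and _closes_new_triangle(
                    tables, cand if kind == "mirna_tf" else cand, kind, truth.planted_ffls
                ):
                    continue
                getattr(tables, kind).add(cand)
                added += 1
            if added < n_decoy and not allow_decoy_triangles:
                raise ConfigError(
                    f"could not place {n_decoy} triangle-free decoy edges in "
                    f"{kind}; lower edge_noise_frac or allow decoy triangles"
                )
    return tables, truth


# ---------------------------------------------------------------------------
# geneset library
# ---------------------------------------------------------------------------

def gen_geneset_library(
    cfg: SynthConfig,
    target_genes: set[str],
    universe: list[str] | None = None,
    n_background: int = 5,
    background_size: int = 25,
) -> dict[str, list[str]]:
    """Build a small geneset library: one set equal to ``target_genes``
    (the planted 'vascular calcification core') plus random background sets
    drawn from ``universe``.  Returns name -> sorted member list, ready for
    GMT serialization."""
    cfg.validate()
    if not target_genes:
        raise ConfigError("target_genes must be nonempty")
    rng = np.random.default_rng([cfg.seed, 3])
    uni = list(universe) if universe is not None else gene_ids(cfg.n_genes)
    if not uni:
        raise ConfigError("universe must be nonempty")
    sets: dict[str, list[str]] = {
        "VC_CORE": sorted({g.strip().upper() for g in target_genes})
    }
    size = min(background_size, len(uni))
    for k in range(1, n_background + 1):
        idx = rng.choice(len(uni), size=size, replace=False)
        sets[f"BACKGROUND_{k:02d}"] = sorted(uni[i] for i in np.sort(idx))
    return sets


# ---------------------------------------------------------------------------
# PPI edge list
# ---------------------------------------------------------------------------

def gen_ppi_edges(
    cfg: SynthConfig,
    target_genes: set[str],
    universe: list[str] | None = None,
    target_density: float = 0.3,
    n_low_confidence: int = 50,
) -> pd.DataFrame:
    """Scored PPI edge list: target-gene pairs interact at
    ``target_density`` with combined scores above medium confidence
    (uniform on 0.45-0.99), plus low-confidence decoy edges (scores below
    0.4) among random universe genes that a medium-confidence threshold
    must discard.  Columns: proteinA, proteinB, combined_score."""
    cfg.validate()
    if not target_genes:
        raise ConfigError("target_genes must be nonempty")
    rng = np.random.default_rng([cfg.seed, 4])
    targets = sorted({g.strip().upper() for g in target_genes})
    uni = list(universe) if universe is not None else gene_ids(cfg.n_genes)
    rows = []
    for i in range(len(targets)):
        for j in range(i + 1, len(targets)):
            if rng.random() < target_density:
                rows.append(
                    (targets[i], targets[j],
                     round(float(rng.uniform(0.45, 0.99)), 3))
                )
    decoy_pool = [g for g in uni if g.strip().upper() not in set(targets)] or uni
    for _ in range(n_low_confidence):
        a = decoy_pool[int(rng.integers(len(decoy_pool)))]
        b = decoy_pool[int(rng.integers(len(decoy_pool)))]
        if a == b:
            continue
        rows.append((a, b, round(float(rng.uniform(0.05, 0.40)), 3)))
    return pd.DataFrame(rows, columns=["proteinA", "proteinB", "combined_score"])


# ---------------------------------------------------------------------------
# serialization of interaction tables
# ---------------------------------------------------------------------------

def write_interaction_tsvs(tables: InteractionTables, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(sorted(tables.mirna_mrna), columns=["mirna", "mrna"]).to_csv(
        outdir / "mirna_mrna.tsv", sep="\t", index=False
    )
    pd.DataFrame(sorted(tables.tf_mrna), columns=["tf", "mrna"]).to_csv(
        outdir / "tf_mrna.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        sorted(tables.mirna_tf), columns=["mirna", "tf", "direction"]
    ).to_csv(outdir / "mirna_tf.tsv", sep="\t", index=False)


def read_interaction_tsvs(
    mirna_mrna: str | Path, tf_mrna: str | Path, mirna_tf: str | Path
) -> InteractionTables:
    mm = pd.read_csv(mirna_mrna, sep="\t", dtype=str)
    tm = pd.read_csv(tf_mrna, sep="\t", dtype=str)
    mt = pd.read_csv(mirna_tf, sep="\t", dtype=str)
    tables = InteractionTables()
    tables.mirna_mrna = {(r.iloc[0], r.iloc[1].upper()) for _, r in mm.iterrows()}
    tables.tf_mrna = {(r.iloc[0].upper(), r.iloc[1].upper()) for _, r in tm.iterrows()}
    for _, r in mt.iterrows():
        direction = r.iloc[2] if len(r) > 2 and pd.notna(r.iloc[2]) else MIRNA_REPRESSES_TF
        tables.mirna_tf.add((r.iloc[0], r.iloc[1].upper(), direction))
    return tables
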