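"""The biDCG iterative two-way re-clustering engine.

The procedure couples clustering of the two axes of an expression matrix:

1. for a sample class C, build a DCG-tree over all genes with features
   restricted to the columns in C;
2. for each candidate gene subgroup g read off the gene tree, build a
   DCG-tree over all samples with features restricted to g;
3. if the sample tree contains a branch made up exclusively of members of
   C, the pair (g, branch) is a dual relationship — a bicluster;
4. repeat for every class of the current sample partition;
5. refresh the sample partition from the accepted branches and sweep again
   until the bicluster collection is stable.

Accepted pairs must also be *active*: the rectangle's mean expression must
exceed the gene group's mean outside the branch and the branch's mean
outside the gene group. This keeps complement gene groups (which trivially
isolate a class by their shared silence) out of the output; it can be
switched off for data where down-regulated signatures are of interest.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .core import Bicluster, BiclusterSet, ExpressionMatrix, Partition
from .dcg import DCGConfig, DCGTree, build_dcg_tree
from .distances import pairwise_distances

log = logging.getLogger(__name__)

__all__ = [
    "BidcgConfig",
    "BidcgResult",
    "initial_sample_partition",
    "gene_tree_for_class",
    "candidate_gene_groups",
    "sample_tree_for_genes",
    "check_dual_relationship",
    "naive_dcg_biclusters",
    "run_bidcg",
    "reorder_heatmap",
    "BiDCG",
    "BiDCGResults",
]


@dataclass(frozen=True)
class BidcgConfig:
    """Engine configuration.

    branch_purity is the fraction of a qualifying branch's samples that
    must belong to the input class (1.0 = strict exclusivity; lower values
    let a branch extend past its seeding class, which overlapping modules
    require). coverage_fraction, when set, additionally requires the branch
    to cover that fraction of the class. max_tree_work caps the total
    clustering effort of one fit — the sum of (item count)^2 over all
    distance trees built — so that inputs which keep proposing fresh probe
    classes cannot run away; the default allows roughly one hundred
    100-item trees.
    """

    gene_metric: str = "euclidean"
    sample_metric: str = "euclidean"
    min_gene_group_size: int = 2
    min_branch_size: int = 2
    branch_purity: float = 0.5
    coverage_fraction: float | None = None
    require_elevated: bool = True
    max_sweeps: int = 10
    max_tree_work: float = 1e6
    dedup_jaccard: float = 0.9
    dcg: DCGConfig = field(default_factory=DCGConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")
        if self.min_gene_group_size < 2:
            raise ValueError("min_gene_group_size must be >= 2")
        if not 0 < self.branch_purity <= 1:
            raise ValueError("branch_purity must lie in (0, 1]")
        if self.coverage_fraction is not None and not (0 < self.coverage_fraction <= 1):
            raise ValueError("coverage_fraction must lie in (0, 1]")


@dataclass
class BidcgResult:
    biclusters: BiclusterSet
    sample_partition: Partition
    n_sweeps: int
    converged: bool
    audit: list[dict]


def _stable_seed(base: int, *keys) -> int:
    h = zlib.crc32(repr(tuple(sorted(map(str, k)) if isinstance(k, (set, frozenset))
                               else k for k in keys)).encode())
    return int((base * 2654435761 + h) % 2**31)


def _dcg_for(cfg: BidcgConfig, *keys) -> DCGConfig:
    return replace(cfg.dcg, seed=_stable_seed(cfg.seed + cfg.dcg.seed, *keys))


def initial_sample_partition(m: ExpressionMatrix, cfg: BidcgConfig,
                             labels: Partition | None = None) -> Partition:
    """Unsupervised seeding: the best-separated level of a DCG-tree on
    samples over all genes (or supplied class labels, supervised mode).

    The level with the highest silhouette on the sample distances is used
    rather than the finest one: an over-split seed class can never be
    matched exactly by a pure branch in the dual-relationship test, whereas
    an over-coarse one is refined by later sweeps.
    """
    if labels is not None:
        if set(labels.items) != set(m.sample_ids):
            raise ValueError("supplied labels do not cover the sample set")
        return labels
    if len(m.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    d = pairwise_distances(m, axis="samples", metric=cfg.sample_metric)
    # best-effort seeding: even faint structure is worth proposing, since
    # every class is re-validated by the dual-relationship test downstream
    dcg_cfg = replace(_dcg_for(cfg, "init-samples"), silhouette_floor=0.0)
    tree = build_dcg_tree(d, dcg_cfg)
    return _best_separated_level(tree, d.values)


def _best_separated_level(tree: DCGTree, dvals) -> Partition:
    from .dcg import level_silhouette

    best, best_s = tree.levels[0], -np.inf
    for p in tree.levels:  # ties go to the coarser level
        lab = p.as_labels()
        labels = np.array([lab[i] for i in tree.items])
        s = level_silhouette(np.asarray(dvals), labels)
        if np.isfinite(s) and s >= best_s:
            best, best_s = p, s
    return best


def gene_tree_for_class(m: ExpressionMatrix, sample_class, cfg: BidcgConfig) -> DCGTree:
    """DCG-tree over all genes, distances restricted to the class columns."""
    sample_class = frozenset(sample_class)
    if not sample_class:
        raise ValueError("empty sample class")
    if cfg.gene_metric == "spearman" and len(sample_class) < 3:
        raise ValueError("spearman needs a class of >= 3 samples")
    d = pairwise_distances(m, axis="genes", metric=cfg.gene_metric,
                           feature_subset=sample_class)
    return build_dcg_tree(d, _dcg_for(cfg, "gene-tree", sample_class))


def candidate_gene_groups(tree: DCGTree, cfg: BidcgConfig) -> list[frozenset]:
    """Distinct proper blocks across all tree levels with size >=
    min_gene_group_size, ordered by (level, size descending)."""
    full = frozenset(tree.items)
    out: list[frozenset] = []
    seen: set[frozenset] = set()
    for p in tree.levels:
        for b in sorted(p.blocks, key=lambda s: (-len(s), sorted(s))):
            if len(b) >= cfg.min_gene_group_size and b != full and b not in seen:
                seen.add(b)
                out.append(b)
    return out


def sample_tree_for_genes(m: ExpressionMatrix, gene_group, cfg: BidcgConfig) -> DCGTree:
    """DCG-tree over all samples, features restricted to the gene group."""
    gene_group = frozenset(gene_group)
    if not gene_group:
        raise ValueError("empty gene group")
    if cfg.sample_metric == "spearman" and len(gene_group) < 3:
        raise ValueError("spearman needs a gene group of >= 3 genes")
    d = pairwise_distances(m, axis="samples", metric=cfg.sample_metric,
                           feature_subset=gene_group)
    return build_dcg_tree(d, _dcg_for(cfg, "sample-tree", gene_group))


def check_dual_relationship(tree: DCGTree, sample_class, cfg: BidcgConfig,
                            accept=None) -> tuple[bool, frozenset | None]:
    """Step-3 test: does some tree branch align with the input class?

    A branch qualifies when at least `branch_purity` of its samples belong
    to the class (1.0 reproduces the strict "exclusively members of the
    class" reading; a lower default lets a branch extend past its seeding
    class, which overlapping modules require), it is a proper subset of the
    sample set, it has at least min_branch_size members, and — when
    coverage_fraction is set — it covers that fraction of the class. Among
    qualifying branches the one sharing the most samples with the class
    (ties: higher purity, then larger) is returned; `accept` optionally
    adds a caller-side predicate (the engine requires rectangle activity).
    """
    sample_class = frozenset(sample_class)
    full = frozenset(tree.items)
    best: frozenset | None = None
    best_key: tuple | None = None
    for p in tree.levels:
        for b in p.blocks:
            if b == full or len(b) < cfg.min_branch_size:
                continue  # a qualifying branch must leave samples outside it
            inter = len(b & sample_class)
            if inter < cfg.branch_purity * len(b):
                continue
            if cfg.coverage_fraction is not None and \
                    inter < cfg.coverage_fraction * len(sample_class):
                continue
            if accept is not None and not accept(b):
                continue
            key = (inter, inter / len(b), len(b))
            if best_key is None or key > best_key:
                best, best_key = b, key
    return best is not None, best


def _is_elevated(m: ExpressionMatrix, genes: frozenset, samples: frozenset) -> bool:
    """Activity test for a candidate rectangle: its mean expression must
    exceed the matrix grand mean, the gene group's mean over the remaining
    columns, and the branch's mean over the remaining rows. Operationalizes
    "transcription factor active in exactly these conditions"; near-full
    gene groups and silent complements fail it."""
    gi = m.gene_index(sorted(genes))
    si = m.sample_index(sorted(samples))
    inside = float(m.values[np.ix_(gi, si)].mean())
    if inside <= float(m.values.mean()):
        return False
    other_s = np.setdiff1d(np.arange(m.shape[1]), si)
    other_g = np.setdiff1d(np.arange(m.shape[0]), gi)
    if other_s.size and inside <= float(m.values[np.ix_(gi, other_s)].mean()):
        return False
    if other_g.size and inside <= float(m.values[np.ix_(other_g, si)].mean()):
        return False
    return True


def _jaccard(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter) if inter else 0.0


def _dedup(pairs: list[tuple[frozenset, frozenset]],
           thresh: float) -> list[tuple[frozenset, frozenset]]:
    """Merge near-identical accepted pairs (both Jaccards above `thresh`),
    keeping the earlier/larger representative."""
    kept: list[tuple[frozenset, frozenset]] = []
    for g, s in sorted(pairs, key=lambda p: (-len(p[0]), sorted(p[0]), sorted(p[1]))):
        dup = any(_jaccard(g, g2) > thresh and _jaccard(s, s2) > thresh
                  for g2, s2 in kept)
        if not dup:
            kept.append((g, s))
    return kept


MAX_CLASSES = 60


def _refresh_classes(m: ExpressionMatrix, pairs,
                     sweep0: Partition, extra=()) -> list[frozenset]:
    """Working classes for the next sweep: the accepted branches verbatim
    (they may overlap — an accepted branch is the revised definition of a
    sample subclass), the unions of overlapping branch pairs (probes that
    let partially-discovered overlapping modules widen towards their full
    condition sets; an over-wide probe simply yields no coherent gene
    group and dies), plus the sweep-0 blocks of any still-unclaimed
    samples."""
    classes: list[frozenset] = []
    claimed: set = set()
    for _, s in pairs:
        if s not in classes:
            classes.append(s)
        claimed |= s
    uniq_pairs: list[tuple[frozenset, frozenset]] = []
    for g, s_ in pairs:
        if (g, s_) not in uniq_pairs:
            uniq_pairs.append((g, s_))
    unions: list[frozenset] = []
    for i, (g1, s1) in enumerate(uniq_pairs):
        for g2, s2 in uniq_pairs[i + 1:]:
            # adjacency through either axis of the dual relationship:
            # shared samples, or shared genes (chained overlapping modules)
            if (s1 & s2) or (g1 & g2):
                u = s1 | s2
                if u not in classes and u not in unions and u != s1 and u != s2:
                    unions.append(u)
    unions.sort(key=lambda u: (len(u), sorted(u)))
    probes = unions + [e for e in extra if e not in classes and e not in unions]
    classes += probes[: max(0, MAX_CLASSES - len(classes))]
    residual: dict[frozenset, set] = {}
    for sample in m.sample_ids:
        if sample not in claimed:
            residual.setdefault(sweep0.block_of(sample), set()).add(sample)
    classes += [frozenset(b) for b in residual.values()]
    return classes


def _rect_contrast(m: ExpressionMatrix, genes: frozenset, samples: frozenset) -> float:
    """Mean expression inside the rectangle minus the larger of the gene
    group's outside-column mean and the branch's outside-row mean."""
    gi = m.gene_index(sorted(genes))
    si = m.sample_index(sorted(samples))
    inside = float(m.values[np.ix_(gi, si)].mean())
    other_s = np.setdiff1d(np.arange(m.shape[1]), si)
    other_g = np.setdiff1d(np.arange(m.shape[0]), gi)
    out = -np.inf
    if other_s.size:
        out = max(out, float(m.values[np.ix_(gi, other_s)].mean()))
    if other_g.size:
        out = max(out, float(m.values[np.ix_(other_g, si)].mean()))
    if not np.isfinite(out):
        out = float(m.values.mean())
    return inside - out


def _prune_subsumed(pairs: list[tuple[frozenset, frozenset]],
                    m: ExpressionMatrix,
                    cell_overlap: float = 0.5) -> list[tuple[frozenset, frozenset]]:
    """Rectangle competition: when two accepted rectangles overlap in at
    least `cell_overlap` of the weaker one's cells, the one with the lower
    contrast (then the smaller) is dropped. Narrow band rectangles and
    merged multi-module rectangles — intermediate readings of heavily
    overlapping modules — lose to the coherent maximal module rectangles;
    disjoint biclusters (including multiple gene signatures for one sample
    class) are never pruned."""
    scored = sorted(
        pairs,
        key=lambda p: (-_rect_contrast(m, p[0], p[1]),
                       -(len(p[0]) * len(p[1])), sorted(p[0]), sorted(p[1])),
    )
    kept: list[tuple[frozenset, frozenset]] = []
    for g, s in scored:
        area = len(g) * len(s)
        dominated = False
        for g2, s2 in kept:
            inter = len(g & g2) * len(s & s2)
            if inter >= cell_overlap * area:
                dominated = True
                break
        if not dominated:
            kept.append((g, s))
    return [p for p in pairs if p in kept]


def _refresh_partition(m: ExpressionMatrix, pairs, sweep0: Partition,
                       cfg: BidcgConfig) -> Partition:
    """New sample partition from accepted branches; a sample claimed by
    several branches goes to the branch whose gene set places it closest to
    the branch's other members; unclaimed samples stay grouped by their
    sweep-0 block."""
    branches: list[tuple[frozenset, frozenset]] = []  # (samples, genes)
    for g, s in pairs:
        if not any(s == s2 for s2, _ in branches):
            branches.append((s, g))
    assign: dict[str, int] = {}
    for sample in m.sample_ids:
        claims = [bi for bi, (s, _) in enumerate(branches) if sample in s]
        if len(claims) == 1:
            assign[sample] = claims[0]
        elif len(claims) > 1:
            best, best_d = claims[0], np.inf
            for bi in claims:
                s, g = branches[bi]
                gi = m.gene_index(sorted(g))
                others = sorted(s - {sample})
                if not others:
                    dist = 0.0
                else:
                    v = m.values[np.ix_(gi, m.sample_index([sample]))][:, 0]
                    rest = m.values[np.ix_(gi, m.sample_index(others))]
                    dist = float(np.linalg.norm(rest - v[:, None], axis=0).mean())
                if dist < best_d:
                    best, best_d = bi, dist
            assign[sample] = best
    blocks: list[set] = [set() for _ in branches]
    for sample, bi in assign.items():
        blocks[bi].add(sample)
    residual: dict[frozenset, set] = {}
    for sample in m.sample_ids:
        if sample not in assign:
            residual.setdefault(sweep0.block_of(sample), set()).add(sample)
    all_blocks = [frozenset(b) for b in blocks if b]
    all_blocks += [frozenset(b) for b in residual.values()]
    # drop duplicates while preserving order
    uniq: list[frozenset] = []
    for b in all_blocks:
        if b not in uniq:
            uniq.append(b)
    return Partition(list(m.sample_ids), uniq)


def run_bidcg(m: ExpressionMatrix, cfg: BidcgConfig | None = None,
              initial_labels: Partition | None = None,
              orientation: str = "samples") -> BidcgResult:
    """Run the full iterative biclustering loop.

    orientation="samples" seeds the loop with a partition of the samples
    (classes are sample sets, candidate subgroups are gene sets);
    orientation="genes" swaps the two roles end to end.
    """
    cfg = cfg or BidcgConfig()
    if orientation not in ("samples", "genes"):
        raise ValueError("orientation must be 'samples' or 'genes'")
    if orientation == "genes":
        swapped = replace(cfg, gene_metric=cfg.sample_metric,
                          sample_metric=cfg.gene_metric)
        res = run_bidcg(m.transpose(), swapped, initial_labels, "samples")
        flipped = BiclusterSet(
            [Bicluster(b.sample_ids, b.gene_ids, b.label) for b in res.biclusters],
            (m.shape[0], m.shape[1]),
        )
        return BidcgResult(flipped, res.sample_partition, res.n_sweeps,
                           res.converged, res.audit)
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")

    sweep0 = initial_sample_partition(m, cfg, initial_labels)
    # working classes may overlap once branches are adopted as classes
    class_list: list[frozenset] = list(sweep0.blocks)
    accepted: list[tuple[frozenset, frozenset]] = []
    prev_all: list[tuple[frozenset, frozenset]] = []
    audit: list[dict] = []
    gene_tree_cache: dict[frozenset, DCGTree] = {}
    sample_tree_cache: dict[frozenset, DCGTree] = {}
    converged = False
    sweep = 0
    work_done = 0.0
    budget_spent = False
    for sweep in range(1, cfg.max_sweeps + 1):
        new: list[tuple[frozenset, frozenset]] = []
        classes = sorted(class_list, key=lambda b: (-len(b), sorted(b)))
        for cls in classes:
            if cfg.gene_metric == "spearman" and len(cls) < 3:
                continue
            budget_spent = work_done >= cfg.max_tree_work
            if budget_spent:
                break
            if cls not in gene_tree_cache:
                try:
                    gene_tree_cache[cls] = gene_tree_for_class(m, cls, cfg)
                except ValueError as err:
                    # e.g. a constant restricted profile under Spearman
                    log.debug("skipping class %s: %s", sorted(cls), err)
                    gene_tree_cache[cls] = None
                work_done += m.shape[0] ** 2
            gtree = gene_tree_cache[cls]
            if gtree is None:
                continue
            for g in candidate_gene_groups(gtree, cfg):
                if cfg.sample_metric == "spearman" and len(g) < 3:
                    continue  # too few features for a rank correlation
                if g not in sample_tree_cache:
                    if work_done >= cfg.max_tree_work:
                        budget_spent = True
                        break
                    try:
                        sample_tree_cache[g] = sample_tree_for_genes(m, g, cfg)
                    except ValueError as err:
                        log.debug("skipping gene group %s: %s", sorted(g), err)
                        sample_tree_cache[g] = None
                    work_done += m.shape[1] ** 2
                stree = sample_tree_cache[g]
                if stree is None:
                    continue
                accept = ((lambda b: _is_elevated(m, g, b))
                          if cfg.require_elevated else None)
                ok, branch = check_dual_relationship(stree, cls, cfg, accept)
                active = bool(ok)
                audit.append({
                    "sweep": sweep, "class": sorted(cls), "genes": sorted(g),
                    "dual": bool(ok), "accepted": active,
                    "branch": sorted(branch) if branch else None,
                })
                if active:
                    new.append((g, branch))
        new_all = _dedup(new, cfg.dedup_jaccard)
        accepted = _prune_subsumed(new_all, m)
        # convergence is judged on the pre-competition collection: the
        # reported set can stabilize while wider probes are still growing
        if set(new_all) == set(prev_all):
            converged = True
            break
        if budget_spent:
            # deterministic work cap: a noisy input can keep proposing new
            # probe classes indefinitely; stop once the tree budget is gone
            log.warning("tree work budget (%.0f) exhausted after sweep %d",
                        cfg.max_tree_work, sweep)
            break
        prev_all = new_all
        # probe classes are refreshed from the pre-competition list so that
        # intermediate readings keep seeding wider probes
        class_list = _refresh_classes(m, new_all, sweep0)
    bset = BiclusterSet(
        [Bicluster(g, s, f"B{k:02d}") for k, (g, s) in enumerate(accepted)],
        m.shape,
    )
    final_partition = (_refresh_partition(m, accepted, sweep0, cfg)
                       if accepted else sweep0)
    return BidcgResult(bset, final_partition, sweep, converged, audit)


def naive_dcg_biclusters(m: ExpressionMatrix,
                         cfg: BidcgConfig | None = None) -> BiclusterSet:
    """Single-pass baseline: biclusters from two independent DCG-trees.

    Genes are clustered once over all samples and samples once over all
    genes; each gene block is paired with the sample block giving the
    highest rectangle contrast, keeping only active rectangles. This is
    the estimate the iterative loop starts from, and the reference against
    which refinement gains are measured.
    """
    cfg = cfg or BidcgConfig()
    gd = pairwise_distances(m, axis="genes", metric=cfg.gene_metric)
    gtree = build_dcg_tree(gd, _dcg_for(cfg, "naive-genes"))
    spart = initial_sample_partition(m, cfg)
    out: list[Bicluster] = []
    k = 0
    for gb in gtree.levels[0].blocks:
        if len(gb) < cfg.min_gene_group_size:
            continue
        best, best_c = None, -np.inf
        for sb in spart.blocks:
            c = _rect_contrast(m, gb, sb)
            if c > best_c:
                best, best_c = sb, c
        if best is None or (cfg.require_elevated and not _is_elevated(m, gb, best)):
            continue
        out.append(Bicluster(gb, best, f"N{k:02d}"))
        k += 1
    return BiclusterSet(out, m.shape)


def reorder_heatmap(m: ExpressionMatrix, b: BiclusterSet):
    """Permutations putting each bicluster's rows/columns together.

    Biclusters are placed block-diagonally in collection order; a gene or
    sample already placed by an earlier (overlapping) bicluster is not
    moved, so chains of overlapping biclusters share their overlap region
    between consecutive blocks. Returns (row_perm, col_perm, rectangles)
    where rectangles[k] = (r0, r1, c0, c1) is bicluster k's bounding
    rectangle in permuted coordinates (half-open).
    """
    b.validate_against(m)
    row_order: list[str] = []
    col_order: list[str] = []
    placed_g: set = set()
    placed_s: set = set()
    for bc in b:
        for g in sorted(bc.gene_ids):
            if g not in placed_g:
                placed_g.add(g)
                row_order.append(g)
        for s in sorted(bc.sample_ids):
            if s not in placed_s:
                placed_s.add(s)
                col_order.append(s)
    row_order += [g for g in m.gene_ids if g not in placed_g]
    col_order += [s for s in m.sample_ids if s not in placed_s]
    rpos = {g: i for i, g in enumerate(row_order)}
    cpos = {s: i for i, s in enumerate(col_order)}
    rects = []
    for bc in b:
        rr = [rpos[g] for g in bc.gene_ids]
        cc = [cpos[s] for s in bc.sample_ids]
        rects.append((min(rr), max(rr) + 1, min(cc), max(cc) + 1))
    row_perm = m.gene_index(row_order)
    col_perm = m.sample_index(col_order)
    return row_perm, col_perm, rects


# ---------------------------------------------------------------------------
# model facade


class BiDCG:
    """Two-way biclustering model over one expression matrix.

    Parameters
    ----------
    data : ExpressionMatrix or pandas.DataFrame
        Genes in rows, samples in columns.
    config : BidcgConfig, optional
    **overrides
        Field overrides applied on top of `config` (e.g. seed=3,
        sample_metric="spearman").
    """

    def __init__(self, data, config: BidcgConfig | None = None, **overrides):
        if isinstance(data, ExpressionMatrix):
            self.matrix = data
        else:
            self.matrix = ExpressionMatrix.from_frame(data)
        cfg = config or BidcgConfig()
        if overrides:
            dcg_over = {k: v for k, v in overrides.items()
                        if k in DCGConfig.__dataclass_fields__
                        and k not in BidcgConfig.__dataclass_fields__}
            top = {k: v for k, v in overrides.items()
                   if k in BidcgConfig.__dataclass_fields__}
            unknown = set(overrides) - set(dcg_over) - set(top)
            if unknown:
                raise TypeError(f"unknown configuration fields: {sorted(unknown)}")
            if dcg_over:
                top["dcg"] = replace(top.get("dcg", cfg.dcg), **dcg_over)
            cfg = replace(cfg, **top)
        self.config = cfg

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "BiDCG":
        return cls(df, **kwargs)

    @classmethod
    def from_tsv(cls, path, delimiter: str = "\t", **kwargs) -> "BiDCG":
        from .core import read_expression_matrix

        return cls(read_expression_matrix(path, delimiter), **kwargs)

    def fit(self, initial_labels: Partition | None = None,
            orientation: str = "samples") -> "BiDCGResults":
        res = run_bidcg(self.matrix, self.config, initial_labels, orientation)
        return BiDCGResults(self, res)


class BiDCGResults:
    """Fitted biclustering: the collection of dual relationships plus the
    final sample partition and sweep diagnostics."""

    def __init__(self, model: BiDCG, raw: BidcgResult):
        self.model = model
        self._raw = raw

    @property
    def biclusters(self) -> BiclusterSet:
        return self._raw.biclusters

    @property
    def sample_partition(self) -> Partition:
        return self._raw.sample_partition

    @property
    def n_sweeps(self) -> int:
        return self._raw.n_sweeps

    @property
    def converged(self) -> bool:
        return self._raw.converged

    @property
    def audit(self) -> list[dict]:
        return self._raw.audit

    def scores(self, truth: BiclusterSet, mode: str = "genes"):
        from .scoring import relevance_and_recovery

        return relevance_and_recovery(self.biclusters, truth, mode)

    def reorder(self):
        return reorder_heatmap(self.model.matrix, self.biclusters)

    def plot_heatmap(self, ax=None, cmap: str = "viridis", boxes: bool = True):
        """Reordered heat map with bicluster rectangles outlined."""
        import matplotlib.pyplot as plt
        from matplotlib.patches import Rectangle

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        rp, cp, rects = self.reorder()
        ax.imshow(self.model.matrix.values[np.ix_(rp, cp)], cmap=cmap,
                  aspect="auto", interpolation="nearest")
        if boxes:
            for (r0, r1, c0, c1) in rects:
                ax.add_patch(Rectangle((c0 - 0.5, r0 - 0.5), c1 - c0, r1 - r0,
                                       fill=False, edgecolor="white", lw=1.2))
        ax.set_xlabel("samples (reordered)")
        ax.set_ylabel("genes (reordered)")
        return ax

    def summary(self) -> str:
        m = self.model.matrix
        lines = [
            "biDCG biclustering results",
            "=" * 54,
            f"matrix:            {m.shape[0]} genes x {m.shape[1]} samples",
            f"metric (genes):    {self.model.config.gene_metric}",
            f"metric (samples):  {self.model.config.sample_metric}",
            f"sweeps:            {self.n_sweeps}"
            + ("" if self.converged else "  (NOT converged)"),
            f"biclusters:        {len(self.biclusters)}",
            f"sample classes:    {len(self.sample_partition)}",
            "-" * 54,
            f"{'label':<8}{'n_genes':>8}{'n_samples':>10}  members (samples)",
        ]
        for b in self.biclusters:
            samples = ",".join(sorted(b.sample_ids))
            if len(samples) > 28:
                samples = samples[:25] + "..."
            lines.append(f"{b.label:<8}{len(b.gene_ids):>8}"
                         f"{len(b.sample_ids):>10}  {samples}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<BiDCGResults: {len(self.biclusters)} biclusters, "
                f"{self.n_sweeps} sweeps, converged={self.converged}>")
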