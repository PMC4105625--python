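"""Synthetic transcription-module benchmarks.

Planted-bicluster expression matrices in the style of the classic
transcription-module benchmarks: a set of modules, each a block of genes
regulated by one transcription factor crossed with the conditions in which
that factor is active. Modules are laid out along the diagonal;
consecutive modules may share `overlap` genes and `overlap` conditions.

Two renderings are provided:

* ``constant`` — binary matrix, 1 inside any module, 0 elsewhere;
* ``additive`` — background cells are uniform random integers in [0, b],
  module cells are (b+1) plus a uniform random integer in [0, u], so every
  module cell strictly exceeds every background cell; the matrix is then
  rescaled by the mean module-background contrast so the noise axis is
  shared with the unit-contrast constant rendering.

Element-wise Gaussian noise of a chosen standard deviation is added last.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import Bicluster, BiclusterSet, ExpressionMatrix

__all__ = [
    "ModuleDesign",
    "SyntheticDataset",
    "design_modules",
    "render_constant",
    "render_additive",
    "add_gaussian_noise",
    "generate_dataset",
]

# additive-rendering constants: background integers 0..BACKGROUND_MAX,
# in-module integers BACKGROUND_MAX+1 .. BACKGROUND_MAX+1+MODULE_SPREAD
BACKGROUND_MAX = 9
MODULE_SPREAD = 9


@dataclass(frozen=True)
class ModuleDesign:
    """Layout of planted transcription modules.

    ``activation[t, c]`` is 1 iff transcription factor t is active in
    condition c; ``regulation[g, t]`` is 1 iff factor t regulates gene g.
    Module k is the rectangle {g : regulation[g, k] = 1} x
    {c : activation[k, c] = 1}.
    """

    n_modules: int
    genes_per_module: int
    conditions_per_module: int
    overlap: int
    activation: np.ndarray  # (n_modules, n_conditions)
    regulation: np.ndarray  # (n_genes, n_modules)

    @property
    def n_genes(self) -> int:
        return self.regulation.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.activation.shape[1]

    def gene_ids(self) -> list[str]:
        return [f"g{i:03d}" for i in range(self.n_genes)]

    def condition_ids(self) -> list[str]:
        return [f"c{j:03d}" for j in range(self.n_conditions)]

    def module_mask(self) -> np.ndarray:
        """Boolean (n_genes, n_conditions) union-of-modules membership."""
        return (self.regulation @ self.activation) > 0

    def truth_biclusters(self) -> BiclusterSet:
        genes = np.array(self.gene_ids())
        conds = np.array(self.condition_ids())
        out = []
        for k in range(self.n_modules):
            out.append(
                Bicluster(
                    frozenset(genes[self.regulation[:, k] > 0]),
                    frozenset(conds[self.activation[k] > 0]),
                    label=f"module_{k:02d}",
                )
            )
        return BiclusterSet(out, (self.n_genes, self.n_conditions))


@dataclass(frozen=True)
class SyntheticDataset:
    matrix: ExpressionMatrix
    truth: BiclusterSet
    design: ModuleDesign
    scenario: str
    noise_sd: float
    seed: int | None


def design_modules(
    n_modules: int,
    genes_per_module: int,
    conditions_per_module: int,
    overlap: int = 0,
) -> ModuleDesign:
    """Diagonal module layout; consecutive modules share `overlap` genes and
    `overlap` conditions, so totals are n*g - (n-1)*overlap genes and
    n*c - (n-1)*overlap conditions."""
    if n_modules < 1 or genes_per_module < 1 or conditions_per_module < 1:
        raise ValueError("module counts and sizes must be positive")
    if overlap < 0 or overlap >= min(genes_per_module, conditions_per_module):
        raise ValueError(
            "overlap must satisfy 0 <= overlap < min(genes_per_module, "
            "conditions_per_module)"
        )
    g_step = genes_per_module - overlap
    c_step = conditions_per_module - overlap
    n_genes = n_modules * genes_per_module - (n_modules - 1) * overlap
    n_conds = n_modules * conditions_per_module - (n_modules - 1) * overlap
    regulation = np.zeros((n_genes, n_modules), dtype=np.int8)
    activation = np.zeros((n_modules, n_conds), dtype=np.int8)
    for k in range(n_modules):
        regulation[k * g_step : k * g_step + genes_per_module, k] = 1
        activation[k, k * c_step : k * c_step + conditions_per_module] = 1
    return ModuleDesign(
        n_modules, genes_per_module, conditions_per_module, overlap,
        activation, regulation,
    )


def _dataset(design: ModuleDesign, values: np.ndarray, scenario: str,
             seed: int | None) -> SyntheticDataset:
    m = ExpressionMatrix(values, design.gene_ids(), design.condition_ids())
    return SyntheticDataset(m, design.truth_biclusters(), design, scenario, 0.0, seed)


def render_constant(design: ModuleDesign) -> SyntheticDataset:
    """Binary rendering: 1 inside any module, 0 outside. Deterministic."""
    values = design.module_mask().astype(float)
    return _dataset(design, values, "constant", None)


def render_additive(design: ModuleDesign, seed: int,
                    background_max: int = BACKGROUND_MAX,
                    module_spread: int = MODULE_SPREAD) -> SyntheticDataset:
    """Additive rendering: integer background, strictly higher integer
    modules, rescaled so the mean module-over-background contrast is 1.

    Background cells are uniform integers on [0, background_max]; module
    cells are (background_max + 1) plus a uniform integer on
    [0, module_spread]. The matrix is then divided by the difference of the
    two means, which puts the additive scenario on the same unit-contrast
    scale as the binary constant scenario, so a given Gaussian noise level
    perturbs both renderings comparably. A cell belonging to more than one
    module is drawn once (membership union), preserving the
    module-over-background separation.
    """
    rng = np.random.default_rng(seed)
    mask = design.module_mask()
    values = rng.integers(0, background_max + 1, size=mask.shape).astype(float)
    n_in = int(mask.sum())
    values[mask] = (background_max + 1) + rng.integers(0, module_spread + 1, size=n_in)
    contrast = (background_max + 1 + module_spread / 2.0) - background_max / 2.0
    values /= contrast
    return _dataset(design, values, "additive", seed)


def add_gaussian_noise(ds: SyntheticDataset, sd: float, seed: int) -> SyntheticDataset:
    """Add i.i.d. Normal(0, sd^2) to every matrix element; truth unchanged."""
    if sd < 0:
        raise ValueError("noise standard deviation must be nonnegative")
    if sd == 0:
        return replace(ds, noise_sd=0.0)
    rng = np.random.default_rng(seed)
    noisy = ds.matrix.values + rng.normal(0.0, sd, size=ds.matrix.shape)
    m = ExpressionMatrix(noisy, ds.matrix.gene_ids, ds.matrix.sample_ids)
    return replace(ds, matrix=m, noise_sd=float(sd))


def generate_dataset(
    scenario: str,
    n_modules: int = 10,
    genes_per_module: int = 10,
    conditions_per_module: int = 5,
    overlap: int = 0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Single entry point: design -> render -> noise, all driven by `seed`."""
    if scenario not in ("constant", "additive"):
        raise ValueError(f"unknown scenario {scenario!r}")
    design = design_modules(n_modules, genes_per_module, conditions_per_module, overlap)
    # independent child seeds for rendering and noise
    ss = np.random.SeedSequence(seed).spawn(2)
    if scenario == "constant":
        ds = render_constant(design)
    else:
        ds = render_additive(design, seed=int(ss[0].generate_state(1)[0] % 2**31))
    ds = add_gaussian_noise(ds, noise_sd, seed=int(ss[1].generate_state(1)[0] % 2**31))
    return replace(ds, seed=seed)
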