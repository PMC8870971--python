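"""Synthetic multiclass matrices with planted class-specific patterns.

Real multiclass tables (clinical measurement panels, signal features,
image-segment statistics) mix class-specific local structure — subsets of
attributes that co-vary within a class — with attribute-level noise.  The
generator emulates exactly that: an equicorrelated Gaussian background
(standard-normal marginals sharing a per-sample latent factor, like the
global inter-correlation of measurement panels) plus *planted blocks*, each
tying a subset of attributes to fixed discretization levels for the carrier
samples of one class.  A class with several blocks on disjoint carrier
sub-groups is a mixture of local patterns rather than one global profile.

Planted cells are placed at the centers of the bins that equal-width
discretization will later form.  Because z-scoring is affine per column, bin
boundaries depend only on the column's observed raw range; planted centers
are computed from the background draw's range and lie strictly inside it, so
at ``noise_sd = 0`` every planted cell discretizes back to exactly its
planted level.  Gaussian noise with ``noise_sd > 0`` (on the background's
unit scale) then blurs the pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .matrix_io import LabeledMatrix
from .preprocess import DEFAULT_LEVELS


@dataclass(frozen=True)
class PlantedBlock:
    """One class-specific pattern: fixed levels on an attribute subset.

    ``carrier_fraction`` is the fraction of the class's samples that carry
    the pattern (rounded up, at least one).
    """

    class_index: int
    attributes: tuple[int, ...]
    levels: tuple[int, ...]
    carrier_fraction: float = 1.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic multiclass matrix.

    Defaults describe a modest two-class panel (30 samples per class, 20
    attributes, 7 levels) with moderate cell noise, the scale of a small
    clinical feature table.
    """

    n_classes: int = 2
    samples_per_class: tuple[int, ...] = (30, 30)
    n_attributes: int = 20
    k: int = DEFAULT_LEVELS
    blocks: tuple[PlantedBlock, ...] = ()
    noise_sd: float = 0.3
    background_correlation: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 1 or len(self.samples_per_class) != self.n_classes:
            raise ValidationError("samples_per_class must list one count per class")
        if any(s < 1 for s in self.samples_per_class):
            raise ValidationError("every class needs at least one sample")
        if self.n_attributes < 1:
            raise ValidationError("need at least one attribute")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0 <= self.background_correlation < 1:
            raise ValidationError("background_correlation must be in [0, 1)")
        for b in self.blocks:
            if not 0 <= b.class_index < self.n_classes:
                raise ValidationError(f"block class {b.class_index} out of range")
            if len(b.attributes) != len(b.levels):
                raise ValidationError("block attributes and levels differ in length")
            if any(not 0 <= a < self.n_attributes for a in b.attributes):
                raise ValidationError("block attribute index out of range")
            if any(not 1 <= v <= self.k for v in b.levels):
                raise ValidationError(f"block levels must lie in 1..{self.k}")
            if not 0 < b.carrier_fraction <= 1:
                raise ValidationError("carrier_fraction must be in (0, 1]")

    @property
    def n_samples(self) -> int:
        return int(sum(self.samples_per_class))


def planted_spec(
    n_classes: int = 2,
    samples_per_class: int | tuple[int, ...] = 30,
    n_attributes: int = 20,
    block_size: int = 10,
    n_patterns: int = 3,
    shared_attributes: bool = True,
    carrier_fraction: float = 0.8,
    noise_sd: float = 0.3,
    k: int = DEFAULT_LEVELS,
    seed: int = 0,
) -> SyntheticSpec:
    """Spec with ``n_patterns`` planted sub-patterns per class; a pure
    function of its arguments.

    Each class holds ``n_patterns`` distinct level signatures carried by
    disjoint sub-groups of its samples — the local-feature structure that
    motivates itemset-based imputation: a class is not one global profile
    but a mixture of co-occurring attribute-value patterns.  In total
    ``carrier_fraction`` of each class's samples carry some pattern, split
    evenly across the patterns.

    With ``shared_attributes`` (the default) all patterns live on the same
    leading ``block_size`` attributes — the shape of a measurement panel
    where most features are informative — and the remaining attributes are
    pure background.  With ``shared_attributes=False`` class ``c`` instead
    gets the disjoint run ``c*block_size .. (c+1)*block_size - 1``; with
    ``carrier_fraction=1`` and ``n_patterns=1`` that construction makes
    every planted level exactly recoverable from the class's other carriers.
    Pattern levels are drawn once from the seeded generator.
    """
    if isinstance(samples_per_class, int):
        samples_per_class = (samples_per_class,) * n_classes
    if block_size > n_attributes or (
        not shared_attributes and n_classes * block_size > n_attributes
    ):
        raise ValidationError(
            f"blocks of {block_size} attributes do not fit in "
            f"{n_attributes} attributes"
        )
    if n_patterns < 1:
        raise ValidationError("n_patterns must be >= 1")
    rng = np.random.default_rng(seed)
    blocks = []
    for c in range(n_classes):
        if shared_attributes:
            attrs = tuple(range(block_size))
        else:
            attrs = tuple(range(c * block_size, (c + 1) * block_size))
        for _ in range(n_patterns):
            # signature = pattern-wide base level plus per-attribute jitter:
            # block attributes then co-vary across sub-patterns (severity-
            # gradient structure), so similarity ranking can tell relevant
            # columns from background ones
            base = int(rng.integers(1, k + 1))
            jitter = rng.integers(-1, 2, size=block_size)
            levels = tuple(
                int(np.clip(base + d, 1, k)) for d in jitter
            )
            blocks.append(
                PlantedBlock(c, attrs, levels, carrier_fraction / n_patterns)
            )
    spec = SyntheticSpec(
        n_classes=n_classes,
        samples_per_class=tuple(samples_per_class),
        n_attributes=n_attributes,
        k=k,
        blocks=tuple(blocks),
        noise_sd=noise_sd,
        seed=seed,
    )
    spec.validate()
    return spec


def generate(spec: SyntheticSpec) -> tuple[LabeledMatrix, dict[tuple[int, int], int]]:
    """Draw one matrix from the spec.

    Returns the labeled matrix and the ground truth: planted level per
    planted cell, keyed by (sample, attribute).  Deterministic per
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_attributes
    # equicorrelated background: a per-sample latent factor shared by all
    # attributes (real measurement panels are strongly inter-correlated);
    # marginals stay standard normal
    rho = spec.background_correlation
    values = np.sqrt(1.0 - rho) * rng.standard_normal((n, m))
    if rho > 0:
        values += np.sqrt(rho) * rng.standard_normal((n, 1))
    labels = np.concatenate(
        [np.full(cnt, c, dtype=object) for c, cnt in enumerate(spec.samples_per_class)]
    )
    class_rows = {
        c: np.where(labels == c)[0] for c in range(spec.n_classes)
    }
    # choose carriers first so the bin geometry can be computed from the
    # cells that stay background: planted centers lie strictly inside the
    # background range, so the observed range (hence the equal-width grid)
    # is set by background cells and planted levels are exactly recoverable
    planted: dict[tuple[int, int], int] = {}
    used: dict[int, set[int]] = {c: set() for c in range(spec.n_classes)}
    for block in spec.blocks:
        rows = class_rows[block.class_index]
        n_carriers = max(1, int(np.ceil(block.carrier_fraction * rows.size)))
        # carriers are disjoint across a class's blocks, so each carrier
        # belongs to exactly one sub-pattern and the truth is unambiguous
        avail = np.array(
            [i for i in rows if i not in used[block.class_index]], dtype=int
        )
        if n_carriers > avail.size:
            raise ValidationError(
                f"class {block.class_index} has too few samples for its "
                f"blocks' carrier fractions"
            )
        carriers = rng.choice(avail, size=n_carriers, replace=False)
        used[block.class_index].update(int(i) for i in carriers)
        for a, v in zip(block.attributes, block.levels):
            for i in carriers:
                planted[(int(i), int(a))] = int(v)
    planted_cols = sorted({j for _, j in planted})
    col_min = np.empty(m)
    col_width = np.empty(m)
    for j in range(m):
        rows_bg = [i for i in range(n) if (i, j) not in planted]
        if j in planted_cols and len(rows_bg) < 2:
            raise ValidationError(
                f"attribute {j} is fully planted; at least two background "
                f"cells per planted column are needed to anchor the bin grid"
            )
        bg = values[rows_bg, j]
        col_min[j] = bg.min()
        col_width[j] = (bg.max() - bg.min()) / spec.k
    truth: dict[tuple[int, int], int] = {}
    for (i, a), v in planted.items():
        values[i, a] = col_min[a] + (v - 0.5) * col_width[a]
        truth[(i, a)] = v
    if spec.noise_sd > 0 and truth:
        cells = sorted(truth)
        noise = rng.normal(0.0, spec.noise_sd, size=len(cells))
        for (i, j), e in zip(cells, noise):
            values[i, j] += e
    names = [f"a{j}" for j in range(m)]
    return LabeledMatrix(values, labels, names), truth
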