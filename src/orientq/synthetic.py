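"""Synthetic audit-corpus generator with a planted orientation-type structure.

Emulates the study setting the pipeline targets: a panel of institutions,
each publishing a handful of image-audit texts, where every institution
belongs to one latent orientation type that shifts which statement
categories its texts emphasize.  Ground truth (the type labels and the
emphasis matrix) is returned *beside* the corpus, never embedded in it, so
downstream stages cannot leak it.

Generation model, per institution of type ``t``:

* draw ``records_per_institution`` records, each with
  ``sentences_per_record`` sentences;
* each sentence's category is drawn from the type's emphasis row with
  probability ``1 - noise_rate``, else uniformly over all categories;
* the sentence itself is a slot-filled realization of one of the
  category's templates.

Everything is reproducible from ``seed`` via one ``numpy`` Generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import templates
from .corpus import AuditCorpus, AuditRecord
from .errors import ConfigError

IntOrRange = int | tuple[int, int]


def _as_range(value: IntOrRange, name: str) -> tuple[int, int]:
    if isinstance(value, (int, np.integer)):
        lo = hi = int(value)
    else:
        lo, hi = int(value[0]), int(value[1])
    if lo < 1 or hi < lo:
        raise ConfigError(f"{name} must be a positive int or (lo, hi) with lo <= hi")
    return lo, hi


@dataclass
class GeneratorConfig:
    """Study-design parameters for the synthetic corpus.

    ``emphasis_matrix`` is ``n_types x n_categories`` with rows summing
    to 1: row ``t`` is the category distribution of type ``t``'s sentences
    before noise mixing.
    """

    n_institutions: int
    emphasis_matrix: np.ndarray
    n_types: int = 4
    records_per_institution: IntOrRange = (6, 12)
    n_categories: int = templates.N_CATEGORIES
    sentences_per_record: IntOrRange = (6, 10)
    noise_rate: float = 0.1
    seed: int = 0
    type_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.emphasis_matrix = np.asarray(self.emphasis_matrix, dtype=float)
        if self.n_institutions < 1:
            raise ConfigError("n_institutions must be >= 1")
        if self.n_types < 1:
            raise ConfigError("n_types must be >= 1")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ConfigError("noise_rate must lie in [0, 1]")
        if self.n_categories > templates.N_CATEGORIES:
            raise ConfigError(
                f"n_categories={self.n_categories} exceeds the shipped template "
                f"bank ({templates.N_CATEGORIES} categories)"
            )
        if self.emphasis_matrix.shape != (self.n_types, self.n_categories):
            raise ConfigError(
                "emphasis_matrix shape must be (n_types, n_categories) = "
                f"({self.n_types}, {self.n_categories}), got {self.emphasis_matrix.shape}"
            )
        if np.any(self.emphasis_matrix < 0):
            raise ConfigError("emphasis_matrix must be nonnegative")
        row_sums = self.emphasis_matrix.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise ConfigError("emphasis_matrix rows must sum to 1 (+/- 1e-9)")
        if not self.type_names:
            self.type_names = tuple(f"type_{t}" for t in range(self.n_types))
        elif len(self.type_names) != self.n_types:
            raise ConfigError("type_names length must equal n_types")
        # validate ranges eagerly
        _as_range(self.records_per_institution, "records_per_institution")
        _as_range(self.sentences_per_record, "sentences_per_record")


@dataclass
class GroundTruth:
    """Planted labels emitted beside a generated corpus."""

    labels: dict[str, int]  # institution_id -> type index
    emphasis_matrix: np.ndarray
    type_names: tuple[str, ...]
    #: n_types x n_categories counts of sentence categories actually drawn,
    #: for calibration checks against the emphasis matrix.
    category_counts: np.ndarray = field(default=None)

    def label_name(self, institution_id: str) -> str:
        return self.type_names[self.labels[institution_id]]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "institution_id": list(self.labels),
                "type_index": list(self.labels.values()),
                "type_name": [self.type_names[t] for t in self.labels.values()],
            }
        )


def _balanced_labels(n: int, n_types: int, rng: np.random.Generator) -> np.ndarray:
    """Exactly-balanced type assignment (remainder spread), order shuffled."""
    base = np.arange(n) % n_types
    rng.shuffle(base)
    return base


def generate_corpus(config: GeneratorConfig) -> tuple[AuditCorpus, GroundTruth]:
    """Generate a corpus and its ground truth; reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    rec_lo, rec_hi = _as_range(config.records_per_institution, "records_per_institution")
    sent_lo, sent_hi = _as_range(config.sentences_per_record, "sentences_per_record")

    labels_arr = _balanced_labels(config.n_institutions, config.n_types, rng)
    width = max(4, len(str(config.n_institutions)))
    records: list[AuditRecord] = []
    labels: dict[str, int] = {}
    category_counts = np.zeros((config.n_types, config.n_categories), dtype=int)

    for i in range(config.n_institutions):
        inst_id = f"inst_{i + 1:0{width}d}"
        t = int(labels_arr[i])
        labels[inst_id] = t
        n_rec = int(rng.integers(rec_lo, rec_hi + 1))
        for r in range(n_rec):
            n_sent = int(rng.integers(sent_lo, sent_hi + 1))
            sentences = []
            for _ in range(n_sent):
                if rng.random() < config.noise_rate:
                    cat = int(rng.integers(config.n_categories))
                else:
                    cat = int(rng.choice(config.n_categories, p=config.emphasis_matrix[t]))
                category_counts[t, cat] += 1
                name, tmpl_options = templates.TEMPLATE_BANK[cat]
                tmpl = tmpl_options[int(rng.integers(len(tmpl_options)))]
                sentences.append(templates.realize_template(tmpl, rng) + ".")
            records.append(
                AuditRecord(
                    institution_id=inst_id,
                    record_id=f"{inst_id}_r{r + 1:02d}",
                    text=" ".join(sentences),
                )
            )

    corpus = AuditCorpus(records)
    truth = GroundTruth(
        labels=labels,
        emphasis_matrix=config.emphasis_matrix.copy(),
        type_names=config.type_names,
        category_counts=category_counts,
    )
    return corpus, truth


def default_four_type_config(
    n_institutions: int,
    seed: int,
    noise_rate: float = 0.1,
    own_block_mass: float = 0.70,
) -> GeneratorConfig:
    """The default four-orientation study design.

    Each type concentrates ``own_block_mass`` of its sentence-category
    distribution uniformly on its own category block (interior comfort,
    site layout, landscape, rehabilitation) and spreads the remainder
    uniformly over all other categories — institutions of every type still
    publish some images of everything, as real facilities do.
    """
    if not 0.0 < own_block_mass < 1.0:
        raise ConfigError("own_block_mass must lie in (0, 1)")
    block_names = ("interior", "layout", "landscape", "rehabilitation")
    n_cat = templates.N_CATEGORIES
    emphasis = np.zeros((4, n_cat))
    for t, block in enumerate(block_names):
        members = [templates.category_index(c) for c in templates.CATEGORY_BLOCKS[block]]
        others = [j for j in range(n_cat) if j not in members]
        emphasis[t, members] = own_block_mass / len(members)
        emphasis[t, others] = (1.0 - own_block_mass) / len(others)
    return GeneratorConfig(
        n_institutions=n_institutions,
        emphasis_matrix=emphasis,
        n_types=4,
        noise_rate=noise_rate,
        seed=seed,
        type_names=block_names,
    )
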