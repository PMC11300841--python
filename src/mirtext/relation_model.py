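"""Masked-instance relation classification with single- and multi-task heads.

A relation candidate is one sentence with one miRNA and one disease mention.
Before classification both mentions are replaced by atomic placeholder tokens
(``@MIRNA$`` / ``@DISEASE$``); other mentions in the sentence stay verbatim.
Masking forces the classifier to judge the asserted relation from context
rather than memorizing entity names, and makes the sentence unambiguous when
it contains several candidates.

Two training modes share the code path: single-task (STM; one linear head on
the pooled encoder state) and multi-task (MTM; one head per task over a
shared encoder, batches sampled proportionally to task size). The returned
classifier always scores with the primary head.

Scores are positive-class probabilities, either from a 2-logit softmax head
(default) or a single-logit sigmoid head.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import RelationInstance, RelationLabel, Sentence
from .encoder import (AdamOptimizer, EncoderConfig, LinearHead, TinyEncoder,
                      WordpieceTokenizer, sigmoid, softmax, softmax_xent_grad)

MIRNA_PLACEHOLDER = "@MIRNA$"
DISEASE_PLACEHOLDER = "@DISEASE$"


@dataclass
class MaskedInstance:
    """A relation candidate with its entity pair masked out."""

    masked_text: str
    label: RelationLabel | None
    provenance: str
    original_text: str = ""
    mirna_surface: str = ""
    disease_surface: str = ""
    mirna_span: tuple[int, int] = (0, 0)
    disease_span: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.masked_text.count(MIRNA_PLACEHOLDER) != 1 \
                or self.masked_text.count(DISEASE_PLACEHOLDER) != 1:
            raise ValueError(
                "masked_text must contain exactly one miRNA and one disease "
                "placeholder"
            )

    def unmask(self) -> str:
        """Reconstruct the original sentence from provenance."""
        first, second = sorted(
            [(self.mirna_span, MIRNA_PLACEHOLDER, self.mirna_surface),
             (self.disease_span, DISEASE_PLACEHOLDER, self.disease_surface)])
        text = self.masked_text
        text = text.replace(first[1], first[2], 1)
        text = text.replace(second[1], second[2], 1)
        return text


def make_instances(sentence: Sentence, doc_id: str = "",
                   label: RelationLabel | None = None) -> list[MaskedInstance]:
    """One masked instance per (miRNA, disease) mention pair in a sentence.

    Only the pair under consideration is masked; all other mentions are left
    verbatim. Surrounding whitespace is preserved exactly.
    """
    from .corpus_io import EntityClass

    instances: list[MaskedInstance] = []
    mirnas = sentence.mentions_of(EntityClass.MIRNA)
    diseases = sentence.mentions_of(EntityClass.DISEASE)
    for m_i, mirna in enumerate(mirnas):
        for d_i, disease in enumerate(diseases):
            spans = sorted([
                (mirna.start, mirna.end, MIRNA_PLACEHOLDER),
                (disease.start, disease.end, DISEASE_PLACEHOLDER),
            ])
            text = sentence.text
            for start, end, placeholder in reversed(spans):
                text = text[:start] + placeholder + text[end:]
            instances.append(MaskedInstance(
                masked_text=text,
                label=label,
                provenance=f"{doc_id}#m{m_i}d{d_i}",
                original_text=sentence.text,
                mirna_surface=mirna.surface,
                disease_surface=disease.surface,
                mirna_span=(mirna.start, mirna.end),
                disease_span=(disease.start, disease.end),
            ))
    return instances


def mask_relation_instance(instance: RelationInstance) -> MaskedInstance:
    """Masked view of one labeled relation instance."""
    pair_sentence = Sentence(text=instance.sentence.text,
                             mentions=[instance.mirna, instance.disease])
    masked = make_instances(pair_sentence, doc_id=instance.doc_id,
                            label=instance.label)
    return masked[0]


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------

@dataclass
class RelationModelConfig:
    """Training configuration shared by STM and MTM fine-tuning."""

    max_length: int = 48
    learning_rate: float = 0.02
    epochs: int = 8
    batch_size: int = 8
    seed: int = 0
    width: int = 32
    n_layers: int = 2
    vocab_size: int = 512
    head: str = "softmax"  # "softmax" (2 logits) or "sigmoid" (1 logit)
    pooling: str = "cls"


_LABEL_INDEX = {RelationLabel.NEGATIVE: 0, RelationLabel.POSITIVE: 1}


class RelationClassifier:
    """Pooled-encoder sentence classifier scoring masked relation instances."""

    def __init__(self, tokenizer: WordpieceTokenizer, encoder: TinyEncoder,
                 head: LinearHead, config: RelationModelConfig):
        self.tokenizer = tokenizer
        self.encoder = encoder
        self.head = head
        self.config = config

    def _pooled(self, text: str) -> tuple[np.ndarray, np.ndarray, dict]:
        ids = self.tokenizer.encode_text(text)[: self.config.max_length]
        states, cache = self.encoder.forward(ids)
        return self.encoder.pooled(states), states, cache

    def score(self, masked_text: str) -> float:
        pooled, _states, _cache = self._pooled(masked_text)
        logits = self.head.logits(pooled)
        if self.config.head == "sigmoid":
            return float(sigmoid(logits)[0])
        return float(softmax(logits)[1])


def predict_proba(classifier: RelationClassifier,
                  instances: Sequence[MaskedInstance]) -> np.ndarray:
    """Positive-class probability per instance, order-preserving."""
    for inst in instances:
        if MIRNA_PLACEHOLDER not in inst.masked_text \
                or DISEASE_PLACEHOLDER not in inst.masked_text:
            raise ValueError(f"instance {inst.provenance!r} missing a placeholder")
    return np.array([classifier.score(inst.masked_text) for inst in instances])


# ---------------------------------------------------------------------------
# Fine-tuning (STM / MTM)
# ---------------------------------------------------------------------------

@dataclass
class TaskSpec:
    """One classification task: a name, its corpus, and its own linear head."""

    task_name: str
    instances: list[MaskedInstance]

    def __post_init__(self) -> None:
        labels = {inst.label for inst in self.instances}
        if not labels <= set(_LABEL_INDEX):
            raise ValueError(
                f"task {self.task_name!r} has labels {labels}; only binary "
                "positive/negative tasks are supported"
            )


def _build_tokenizer(texts: list[str], config: RelationModelConfig
                     ) -> WordpieceTokenizer:
    return WordpieceTokenizer.train(
        texts, vocab_size=config.vocab_size,
        atomic_tokens=(MIRNA_PLACEHOLDER, DISEASE_PLACEHOLDER))


def fine_tune_stm(train: Sequence[MaskedInstance],
                  val: Sequence[MaskedInstance],
                  config: RelationModelConfig) -> RelationClassifier:
    """Single-task fine-tuning: one linear head over the pooled encoder state."""
    return fine_tune_mtm(TaskSpec("primary", list(train)), [], config,
                         _require_auxiliary=False)


def fine_tune_mtm(primary: TaskSpec, auxiliary: Sequence[TaskSpec],
                  config: RelationModelConfig,
                  _require_auxiliary: bool = True) -> RelationClassifier:
    """Multi-task fine-tuning over a shared encoder.

    Each task owns a linear head; within an epoch, batches are drawn from all
    tasks proportionally to corpus size in a seed-controlled order. The
    returned classifier scores with the primary head only.
    """
    if _require_auxiliary and not auxiliary:
        raise ValueError("MTM requires at least one auxiliary task")
    if not primary.instances:
        raise ValueError("empty training set")
    tasks = [primary, *auxiliary]

    tokenizer = _build_tokenizer(
        [inst.masked_text for task in tasks for inst in task.instances], config)
    encoder = TinyEncoder(EncoderConfig(
        vocab_size=len(tokenizer), width=config.width,
        n_layers=config.n_layers, max_length=config.max_length,
        pooling=config.pooling, seed=config.seed))
    rng = np.random.default_rng(config.seed + 1)
    n_out = 1 if config.head == "sigmoid" else 2
    heads = [LinearHead.create(config.width, n_out, rng, name=f"head_{t.task_name}")
             for t in tasks]

    params = encoder.parameters()
    for head in heads:
        params |= head.parameters()
    optimizer = AdamOptimizer(params, lr=config.learning_rate)

    for _epoch in range(config.epochs):
        # proportional batch schedule across tasks
        schedule: list[tuple[int, np.ndarray]] = []
        for t_i, task in enumerate(tasks):
            order = rng.permutation(len(task.instances))
            for start in range(0, len(order), config.batch_size):
                schedule.append((t_i, order[start:start + config.batch_size]))
        for s_i in rng.permutation(len(schedule)):
            t_i, batch = schedule[s_i]
            task, head = tasks[t_i], heads[t_i]
            grads = optimizer.zero_grads()
            for idx in batch:
                inst = task.instances[idx]
                ids = tokenizer.encode_text(inst.masked_text)[: config.max_length]
                states, cache = encoder.forward(ids)
                pooled = encoder.pooled(states)
                logits = head.logits(pooled)
                target = _LABEL_INDEX[inst.label]
                if config.head == "sigmoid":
                    prob = sigmoid(logits)[0]
                    d_logits = np.array([prob - target])
                else:
                    _loss, d_logits = softmax_xent_grad(logits, target)
                d_pooled = head.backward(pooled, d_logits, grads)
                d_states = encoder.pooled_grad(states, d_pooled)
                encoder.backward(cache, d_states, grads)
            optimizer.step(grads)

    return RelationClassifier(tokenizer, encoder, heads[0], config)


# ---------------------------------------------------------------------------
# Hyperparameter optimization hook
# ---------------------------------------------------------------------------

@dataclass
class HPOSpace:
    """Search space and budget for the hyperparameter-optimization hook."""

    ranges: dict[str, list]
    objective: str = "auroc"  # maximized
    budget: int = 10
    pruning: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if not self.ranges or any(not v for v in self.ranges.values()):
            raise ValueError("every parameter range must be non-empty")


@dataclass
class Trial:
    trial_id: int
    params: dict
    intermediate: list[float] = field(default_factory=list)
    objective: float | None = None
    pruned: bool = False
    failed: bool = False
    error: str = ""


@dataclass
class HPOResult:
    best_params: dict
    best_objective: float
    trials: list[Trial]


def optimize_hyperparameters(space: HPOSpace, trainer) -> HPOResult:
    """Budgeted search over ``space`` with median pruning.

    ``trainer(params, report)`` trains one configuration and returns the final
    objective value (higher is better). It may call ``report(step, value)``
    with intermediate values; when pruning is enabled and an intermediate
    value falls below the median of earlier trials at the same step, the
    trial is halted by raising :class:`TrialPruned` inside ``report``. A
    pruned trial is never returned as best.
    """
    rng = np.random.default_rng(space.seed)
    trials: list[Trial] = []
    history: dict[int, list[float]] = {}

    for trial_id in range(space.budget):
        params = {key: values[rng.integers(len(values))]
                  for key, values in sorted(space.ranges.items())}
        trial = Trial(trial_id=trial_id, params=params)

        def report(step: int, value: float, _trial=trial) -> None:
            _trial.intermediate.append(value)
            earlier = history.get(step, [])
            if space.pruning and len(earlier) >= 2 \
                    and value < float(np.median(earlier)):
                raise TrialPruned(step)
            history.setdefault(step, []).append(value)

        try:
            trial.objective = float(trainer(params, report))
        except TrialPruned:
            trial.pruned = True
        except Exception as exc:  # noqa: BLE001 - aggregated below
            trial.failed = True
            trial.error = str(exc)
        trials.append(trial)

    completed = [t for t in trials if not t.pruned and not t.failed]
    if not completed:
        failures = [f"trial {t.trial_id}: {t.error or 'pruned'}" for t in trials]
        raise RuntimeError("all trials failed: " + "; ".join(failures))
    best = max(completed, key=lambda t: t.objective)
    return HPOResult(best_params=best.params, best_objective=best.objective,
                     trials=trials)


class TrialPruned(Exception):
    """Raised inside ``report`` to halt an unpromising trial."""
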