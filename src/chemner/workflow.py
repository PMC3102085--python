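"""Typed composition of swappable pipeline components.

A workflow is a linear pipeline of named components, each declaring which
annotation kinds it consumes and produces ({document, tokens, entities}).
Validation checks that every consumed kind is produced earlier (the document
comes from the reader); any two components with identical consumes/produces
signatures are interchangeable — swapping the chemistry tokeniser for the
naive one reruns the identical downstream tagger, which is exactly the
tokenisation-ablation experiment.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .annotations import AnnotatedDocument, SourceDocument
from .memm import MEMMModel, load_model, tag
from .pattern import ChemicalLexicon, NGramScorer, PatternRuleSet, \
    default_rules, recognise
from .tokeniser import TokeniserConfig, naive_tokenise, tokenise

__all__ = ["ComponentSpec", "WorkflowConfig", "ValidationReport", "RunResult",
           "validate", "run", "COMPONENT_REGISTRY", "register_component"]

KINDS = ("document", "tokens", "entities")


@dataclass(frozen=True)
class ComponentSpec:
    name: str
    consumes: frozenset[str]
    produces: frozenset[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.produces:
            raise ValueError(f"component {self.name!r} produces nothing")
        bad = (set(self.consumes) | set(self.produces)) - set(KINDS)
        if bad:
            raise ValueError(f"unknown annotation kinds {sorted(bad)}")


@dataclass
class _ComponentDef:
    consumes: frozenset[str]
    produces: frozenset[str]
    factory: object  # params -> callable(ctx: dict) -> dict updates


COMPONENT_REGISTRY: dict[str, _ComponentDef] = {}


def register_component(name: str, consumes, produces, factory) -> None:
    if name in COMPONENT_REGISTRY:
        raise ValueError(f"component {name!r} already registered")
    COMPONENT_REGISTRY[name] = _ComponentDef(
        consumes=frozenset(consumes), produces=frozenset(produces),
        factory=factory)


def _reader_factory(params):
    def step(ctx):
        if "document" in ctx:  # documents supplied to run()
            return {}
        path = params.get("path")
        if path is None:
            raise ValueError("reader needs documents from run() or a 'path' param")
        from .annotations import read_plain_text
        return {"document": read_plain_text(path)}
    return step


def _chem_tokeniser_factory(params):
    cfg = TokeniserConfig.from_dict(params["config"]) if "config" in params \
        else TokeniserConfig()

    def step(ctx):
        return {"tokens": tokenise(ctx["document"], cfg)}
    return step


def _naive_tokeniser_factory(params):
    def step(ctx):
        return {"tokens": naive_tokenise(ctx["document"])}
    return step


def _memm_tagger_factory(params):
    model = params["model"]
    if not isinstance(model, MEMMModel):
        model = load_model(model)
    threshold = params.get("threshold", 0.3)

    def step(ctx):
        return {"entities": tag(model, ctx["tokens"], threshold=threshold,
                                text=ctx["document"].text)}
    return step


def _pattern_tagger_factory(params):
    lexicon = params["lexicon"]
    if not isinstance(lexicon, ChemicalLexicon):
        words = Path(lexicon).read_text(encoding="utf-8").split("\n")
        stop = params.get("stop_words", ())
        if not isinstance(stop, (tuple, list, set, frozenset)):
            stop = Path(stop).read_text(encoding="utf-8").split("\n")
        lexicon = ChemicalLexicon.from_words(
            [w for w in words if w.strip()], [w for w in stop if w.strip()])
    scorer = params.get("scorer")
    rules = params.get("rules", default_rules())

    def step(ctx):
        return {"entities": recognise(ctx["tokens"], lexicon, scorer=scorer,
                                      rules=rules, text=ctx["document"].text)}
    return step


register_component("reader", (), ("document",), _reader_factory)
register_component("chem_tokeniser", ("document",), ("tokens",),
                   _chem_tokeniser_factory)
register_component("naive_tokeniser", ("document",), ("tokens",),
                   _naive_tokeniser_factory)
register_component("memm_tagger", ("tokens",), ("entities",),
                   _memm_tagger_factory)
register_component("pattern_tagger", ("tokens",), ("entities",),
                   _pattern_tagger_factory)


@dataclass
class WorkflowConfig:
    """Ordered component references with parameter bindings."""

    steps: list[tuple[str, dict]]

    def specs(self) -> list[ComponentSpec]:
        out = []
        for name, params in self.steps:
            if name not in COMPONENT_REGISTRY:
                raise KeyError(f"unknown component {name!r}")
            cd = COMPONENT_REGISTRY[name]
            out.append(ComponentSpec(name=name, consumes=cd.consumes,
                                     produces=cd.produces, params=params))
        return out

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {"pipeline": [{"component": n, "params": p} for n, p in self.steps]},
            sort_keys=True, default_flow_style=False)

    @classmethod
    def from_yaml(cls, text: str) -> "WorkflowConfig":
        data = yaml.safe_load(text)
        return cls(steps=[(s["component"], s.get("params") or {})
                          for s in data["pipeline"]])


@dataclass
class ValidationReport:
    ok: bool
    violations: list[str]
    warnings: list[str]


def validate(workflow: WorkflowConfig) -> ValidationReport:
    """Check that each component's consumed kinds are produced earlier.

    A kind produced twice is legal but warned about — the later producer
    overwrites the earlier one.
    """
    available: set[str] = set()
    violations: list[str] = []
    warnings: list[str] = []
    for spec in workflow.specs():
        for kind in sorted(spec.consumes):
            if kind not in available:
                violations.append(
                    f"component {spec.name!r} requires {kind!r}, which no "
                    f"earlier component produces")
        for kind in sorted(spec.produces):
            if kind in available:
                warnings.append(
                    f"component {spec.name!r} re-produces {kind!r}; "
                    f"the later output wins")
        available |= spec.produces
    return ValidationReport(ok=not violations, violations=violations,
                            warnings=warnings)


@dataclass
class RunResult:
    annotated: list[AnnotatedDocument]
    failures: list[tuple[str, str, str]]  # (doc_id, component, error)
    timings: dict[str, float]


def run(workflow: WorkflowConfig, documents: list[SourceDocument],
        fail_fast: bool = False) -> RunResult:
    """Execute the pipeline per document; deterministic given configs and models.

    A component failure aborts that document and is recorded as a diagnostic;
    the rest of the corpus continues unless ``fail_fast``.
    """
    report = validate(workflow)
    if not report.ok:
        raise ValueError("invalid workflow: " + "; ".join(report.violations))
    steps = [(spec, COMPONENT_REGISTRY[spec.name].factory(spec.params))
             for spec in workflow.specs()]
    annotated: list[AnnotatedDocument] = []
    failures: list[tuple[str, str, str]] = []
    timings: dict[str, float] = {}
    for doc in documents:
        ctx: dict = {"document": doc}
        failed = False
        for spec, step in steps:
            t0 = time.perf_counter()
            try:
                ctx.update(step(ctx))
            except Exception as exc:  # noqa: BLE001 — diagnostics by design
                if fail_fast:
                    raise
                failures.append((doc.doc_id, spec.name, str(exc)))
                failed = True
                break
            finally:
                timings[spec.name] = timings.get(spec.name, 0.0) + (
                    time.perf_counter() - t0)
        if not failed:
            annotated.append(AnnotatedDocument(
                document=ctx["document"], entities=ctx.get("entities", [])))
    return RunResult(annotated=annotated, failures=failures, timings=timings)
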