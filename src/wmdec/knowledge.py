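"""Long-term knowledge: the declarative network and the production-rule engine.

Declarative LTM is a labelled graph (superordinate, subordinate, property,
opposition and sequence links).  Procedural LTM is a set of condition-action
rules written in a small text DSL; conditions are ordered conjunctions of
predicate terms evaluated left to right with single-pass variable binding.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from random import Random

LINK_LABELS = ("SUP", "SUB", "PROP", "OPP", "SEQ")

#: mirror labels added automatically on load
_MIRROR = {"SUB": "SUP", "SUP": "SUB", "OPP": "OPP"}


class LoadError(ValueError):
    """Raised when a declarative or procedural specification is inconsistent."""


@dataclass
class Node:
    """One declarative-LTM entry: a named node with labelled links."""

    name: str
    syllables: int = 0
    strength: float = 0.50
    links: list = field(default_factory=list)  # list of (label, target)

    def targets(self, label: str) -> list:
        return [t for (lab, t) in self.links if lab == label]

    def has_link(self, label: str, target: str) -> bool:
        return (label, target) in self.links


class Network:
    """Declarative LTM as a labelled graph with enforced link symmetry."""

    def __init__(self) -> None:
        self.nodes: dict[str, Node] = {}
        self._prop_cache: dict = {}

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def __getitem__(self, name: str) -> Node:
        return self.nodes[name]

    def get(self, name: str):
        return self.nodes.get(name)

    def add_node(self, node: Node) -> None:
        self.nodes[node.name] = node
        self._prop_cache.clear()

    def is_a(self, name: str, category: str) -> bool:
        """True when `name` carries a SUP or PROP link to `category`."""
        node = self.nodes.get(name)
        if node is None:
            return False
        return node.has_link("SUP", category) or node.has_link("PROP", category)

    def prop(self, name: str, of_class: str):
        """The PROP target of `name` that is itself subordinate to `of_class`."""
        key = (name, of_class)
        try:
            return self._prop_cache[key]
        except KeyError:
            pass
        result = None
        node = self.nodes.get(name)
        if node is not None:
            for target in node.targets("PROP"):
                tn = self.nodes.get(target)
                if tn is not None and tn.has_link("SUP", of_class):
                    result = target
                    break
        self._prop_cache[key] = result
        return result

    def opposites(self, name: str) -> list:
        node = self.nodes.get(name)
        return node.targets("OPP") if node is not None else []

    def to_spec(self) -> str:
        lines = []
        for node in self.nodes.values():
            parts = [node.name, f"syllables={node.syllables}"]
            parts += [f"link={lab}:{t}" for (lab, t) in node.links]
            lines.append(" ".join(parts))
        return "\n".join(lines) + "\n"

    def _complete_links(self) -> None:
        for node in list(self.nodes.values()):
            for lab, target in list(node.links):
                mirror = _MIRROR.get(lab)
                if mirror is None:
                    continue
                other = self.nodes[target]
                if not other.has_link(mirror, node.name):
                    other.links.append((mirror, node.name))


def load_dltm(spec) -> Network:
    """Load a declarative network from a line-oriented node specification.

    Each line: ``NAME syllables=K link=LABEL:TARGET ...``.  Missing mirror
    links (SUB/SUP, symmetric OPP) are added; all strengths are set to 0.50.
    Accepts a string or an iterable of lines.
    """
    if isinstance(spec, str):
        lines = spec.splitlines()
    else:
        lines = list(spec)
    net = Network()
    parsed = []
    for ln, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        name = parts[0]
        if name in net:
            raise LoadError(f"line {ln}: duplicate node {name!r}")
        node = Node(name=name)
        for part in parts[1:]:
            if part.startswith("syllables="):
                node.syllables = int(part.split("=", 1)[1])
            elif part.startswith("link="):
                lab, _, target = part.split("=", 1)[1].partition(":")
                if lab not in LINK_LABELS:
                    raise LoadError(f"line {ln}: unknown link label {lab!r}")
                node.links.append((lab, target))
            else:
                raise LoadError(f"line {ln}: unknown field {part!r}")
        net.add_node(node)
        parsed.append((ln, node))
    for ln, node in parsed:
        for lab, target in node.links:
            if target not in net:
                raise LoadError(
                    f"line {ln}: node {node.name!r} links to undeclared node {target!r}")
    net._complete_links()
    for node in net.nodes.values():
        node.strength = 0.50
    return net


# ---------------------------------------------------------------------------
# Production rules
# ---------------------------------------------------------------------------

@dataclass
class PredicateTerm:
    """One term of a rule condition.

    ``binds`` names the variable receiving the predicate's value; ``negated``
    inverts truth; ``comparison``/``compare_to`` implement ``== / != / >= / <=``
    against a constant or a previously bound variable.
    """

    function: str
    args: tuple
    negated: bool = False
    binds: str | None = None
    comparison: str | None = None
    compare_to: str | None = None


@dataclass
class Action:
    function: str
    args: tuple


@dataclass(eq=False)   # identity semantics: rules live in sets/registries
class ProductionRule:
    name: str
    condition: list            # list of PredicateTerm
    action: Action
    strength: float = 0.5
    duration: int = 1

    def __post_init__(self):
        if not (0.0 <= self.strength <= 1.0):
            raise LoadError(f"rule {self.name}: strength outside [0,1]")
        if self.duration < 1:
            raise LoadError(f"rule {self.name}: duration must be >= 1")


@dataclass
class LearningConfig:
    eta: float = 0.00008
    new_rule_strength: float = 0.05
    new_rule_duration: int = 5


_TERM_RE = re.compile(
    r"^(?:(?P<var>[A-Z][A-Z0-9_]*)\s*=\s*)?"
    r"(?P<neg>!)?"
    r"(?P<fn>[a-z][a-z0-9_]*)\s*\((?P<args>[^)]*)\)"
    r"(?:\s*(?P<cmp>==|!=|>=|<=|>|<)\s*(?P<rhs>\S+))?$"
)


def _parse_term(text: str, rule_name: str, bound: set) -> PredicateTerm:
    m = _TERM_RE.match(text.strip())
    if m is None:
        raise LoadError(f"rule {rule_name}: cannot parse term {text!r}")
    args = tuple(a.strip() for a in m.group("args").split(",") if a.strip())
    for a in args:
        if a[0].isupper() and a.isidentifier() and len(a) == 1 and a not in bound:
            # single-letter uppercase tokens are variables; anything longer is
            # a constant symbol (conventions of the rule DSL)
            raise LoadError(
                f"rule {rule_name}: variable {a!r} used before being bound")
    term = PredicateTerm(
        function=m.group("fn"), args=args,
        negated=m.group("neg") is not None,
        binds=m.group("var"),
        comparison=m.group("cmp"), compare_to=m.group("rhs"))
    if term.binds is not None and term.negated:
        raise LoadError(f"rule {rule_name}: a negated term cannot bind")
    if term.binds is not None:
        bound.add(term.binds)
    return term


def parse_rules(text: str) -> list:
    """Parse the block DSL::

        RULE name strength=S duration=D:
          IF term AND term ... THEN action(args)

    ``!`` negates a term, ``X=`` binds its value.  Whitespace and newlines
    inside a block are free; ``#`` starts a comment.
    """
    # strip comments, then split into RULE blocks
    src = "\n".join(line.split("#", 1)[0] for line in text.splitlines())
    blocks = re.split(r"\bRULE\b", src)
    rules = []
    for block in blocks:
        block = block.strip()
        if not block:
            continue
        head, sep, body = block.partition(":")
        if not sep:
            raise LoadError(f"rule block missing ':' — {block[:40]!r}")
        head_parts = head.split()
        name = head_parts[0]
        strength, duration = 0.5, 1
        for part in head_parts[1:]:
            if part.startswith("strength="):
                strength = float(part.split("=", 1)[1])
            elif part.startswith("duration="):
                duration = int(part.split("=", 1)[1])
            else:
                raise LoadError(f"rule {name}: unknown header field {part!r}")
        body = " ".join(body.split())
        m = re.match(r"^IF\s+(.*?)\s+THEN\s+(.*)$", body)
        if m is None:
            raise LoadError(f"rule {name}: body must be 'IF ... THEN ...'")
        cond_text, act_text = m.group(1), m.group(2)
        bound: set = set()
        terms = [_parse_term(t, name, bound)
                 for t in re.split(r"\s+AND\s+", cond_text)]
        am = re.match(r"^([a-z][a-z0-9_]*)\s*\(([^)]*)\)$", act_text.strip())
        if am is None:
            raise LoadError(f"rule {name}: cannot parse action {act_text!r}")
        act_args = tuple(a.strip() for a in am.group(2).split(",") if a.strip())
        rules.append(ProductionRule(
            name=name, condition=terms,
            action=Action(am.group(1), act_args),
            strength=strength, duration=duration))
    names = [r.name for r in rules]
    if len(set(names)) != len(names):
        raise LoadError("duplicate rule names in rule set")
    return rules


class UnknownPredicateError(LookupError):
    """A rule references a predicate that is not registered."""


def _is_var(token: str) -> bool:
    return len(token) == 1 and token.isupper()


def compile_condition(rule: ProductionRule, registry: dict):
    """Compile a rule condition into a fast closure ``f(state) -> bindings``.

    Semantically identical to :func:`evaluate_condition`; returns the
    bindings dict on match and None otherwise.
    """
    steps = []
    for term in rule.condition:
        fn = registry.get(term.function)
        if fn is None:
            raise UnknownPredicateError(
                f"rule {rule.name}: predicate {term.function!r} "
                "is not registered")
        arg_specs = tuple((_is_var(a), a) for a in term.args)
        cmp_op = term.comparison
        rhs = term.compare_to
        rhs_var = rhs is not None and _is_var(rhs)
        negated = term.negated
        binds = term.binds

        def step(state, b, fn=fn, arg_specs=arg_specs, cmp_op=cmp_op,
                 rhs=rhs, rhs_var=rhs_var, negated=negated, binds=binds):
            args = [b[tok] if isvar else tok for (isvar, tok) in arg_specs]
            value = fn(state, *args)
            if cmp_op is not None:
                value = _compare(value, cmp_op, b[rhs] if rhs_var else rhs)
            if negated:
                if value:
                    return False
                return True
            if not value:
                return False
            if binds is not None:
                b[binds] = value
            return True

        steps.append(step)

    def evaluate(state):
        b: dict = {}
        for step in steps:
            if not step(state, b):
                return None
        return b

    return evaluate


def _resolve(token: str, bindings: dict):
    return bindings.get(token, token)


def evaluate_condition(rule: ProductionRule, state, registry: dict):
    """Evaluate a rule condition left to right against `state`.

    `registry` maps predicate names to callables ``fn(state, *args)`` that
    return a truthy value (possibly a symbol) or a falsy value/None.  Returns
    ``(matched, bindings)``; bindings are only meaningful when matched.
    """
    bindings: dict = {}
    for term in rule.condition:
        fn = registry.get(term.function)
        if fn is None:
            raise UnknownPredicateError(
                f"rule {rule.name}: predicate {term.function!r} is not registered")
        args = [_resolve(a, bindings) for a in term.args]
        value = fn(state, *args)
        if term.comparison is not None:
            rhs = _resolve(term.compare_to, bindings)
            value = _compare(value, term.comparison, rhs)
        ok = (not value) if term.negated else bool(value)
        if not ok:
            return False, {}
        if term.binds is not None:
            bindings[term.binds] = value
    return True, bindings


def _compare(value, op: str, rhs):
    if value is None or value is False:
        return False
    try:
        rhs_cast = type(value)(rhs) if not isinstance(rhs, type(value)) else rhs
    except (TypeError, ValueError):
        rhs_cast = rhs
    if op == "==":
        return value == rhs_cast
    if op == "!=":
        return value != rhs_cast
    if op == ">=":
        return value >= rhs_cast
    if op == "<=":
        return value <= rhs_cast
    if op == ">":
        return value > rhs_cast
    if op == "<":
        return value < rhs_cast
    raise LoadError(f"unknown comparison {op!r}")


def select_rule(matches, active, rng: Random):
    """Select at most one rule for execution.

    `matches` are (rule, bindings) pairs for rules not currently executing;
    the highest-strength rule wins, ties broken uniformly at random.
    """
    candidates = [(r, b) for (r, b) in matches if r not in active]
    if not candidates:
        return None
    best = max(r.strength for r, _ in candidates)
    top = [(r, b) for (r, b) in candidates if r.strength == best]
    if len(top) == 1:
        return top[0]
    return top[rng.randrange(len(top))]


def update_rule_strength(rule: ProductionRule, outcome: str,
                         cfg: LearningConfig) -> float:
    """Strengthen (positive) or weaken (negative) a rule after an episode."""
    s = rule.strength
    if outcome == "positive":
        s = s + (1.0 - s) * cfg.eta
    elif outcome == "negative":
        s = s * (1.0 - cfg.eta)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    rule.strength = min(1.0, max(0.0, s))
    return rule.strength


def association_rule_name(stimulus: str, response: str) -> str:
    return f"assoc-{stimulus}-{response}"


def create_association_rule(stimulus: str, response: str,
                            cfg: LearningConfig, existing) -> ProductionRule | None:
    """Create a direct stimulus-response rule after a successful episode.

    The rule matches when a dominant task set is known, the stimulus is
    accessible in the episodic buffer and motor output is still available;
    it then feeds the response into the automatic stream.  Returns None when
    an equivalent rule already exists.
    """
    name = association_rule_name(stimulus, response)
    names = {r.name for r in existing}
    if name in names:
        return None
    bound: set = set()
    terms = [
        _parse_term("V = domts()", name, bound),
        _parse_term("ltmsup(V, TSKSET)", name, bound),
        _parse_term(f"ebacc({stimulus}, OBJECT, ON)", name, bound),
        _parse_term("gamsget(STATUS) != DONE", name, bound),
    ]
    return ProductionRule(
        name=name, condition=terms,
        action=Action("do", (response,)),
        strength=cfg.new_rule_strength, duration=cfg.new_rule_duration)
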