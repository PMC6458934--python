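"""BNF grammar parsing, genotype-to-word mapping, and the word dialect.

Grammatical evolution (GE) separates the search space (fixed-length integer
*codon* genotypes) from the solution space (words of a context-free grammar).
A genotype is mapped to a word by a depth-first, left-most derivation: at
every choice point with k > 1 alternatives the next unconsumed codon ``c``
selects alternative ``c mod k``; single-alternative rules consume nothing.
If the codons run out while nonterminals remain, the individual is *invalid*
(no wrapping) — invalidity is a value, not an exception.

Words describing network topologies use a compact dialect: ``{`` terminates a
hidden-neuron block, ``(`` terminates each input-synapse configuration within
a block, and ``@`` separates the three fields of a configuration
(``id@weight@delay``).  The last configuration of a block, which has no
trailing ``(``, is the hidden neuron's synapse onto the output neuron.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence, Union

import numpy as np

from .srm import (
    DELAY_MAX,
    DELAY_MIN,
    HiddenNeuronSpec,
    NetworkTopology,
    SynapseSpec,
)

__all__ = [
    "Grammar",
    "Genotype",
    "GrammarError",
    "WordParseError",
    "load_grammar",
    "default_grammar",
    "map_genotype",
    "parse_word",
    "serialize_topology",
    "INVALID",
]

# Sentinel returned by map_genotype when codons are exhausted mid-derivation.
INVALID = None

NT = "NT"
T = "T"
Symbol = tuple[str, str]

_TOKEN_RE = re.compile(r"<[^<>\s]+>|\"[^\"]*\"|'[^']*'|\S+")


class GrammarError(ValueError):
    """Malformed or inconsistent BNF text."""


class WordParseError(ValueError):
    """A word that does not conform to the topology dialect."""


@dataclass(frozen=True)
class Grammar:
    """Productions of a context-free grammar in BNF.

    ``productions`` maps each nonterminal (with angle brackets) to its ordered
    list of alternatives; each alternative is a sequence of (kind, value)
    symbols where kind is ``"NT"`` or ``"T"``.  Alternative order defines
    codon indexing, so it is preserved exactly as written.
    """

    start: str
    productions: dict[str, tuple[tuple[Symbol, ...], ...]]

    @property
    def nonterminals(self) -> tuple[str, ...]:
        return tuple(self.productions)

    @property
    def terminals(self) -> tuple[str, ...]:
        seen: list[str] = []
        for alts in self.productions.values():
            for alt in alts:
                for kind, value in alt:
                    if kind == T and value not in seen:
                        seen.append(value)
        return tuple(seen)


@dataclass(frozen=True)
class Genotype:
    """Fixed-length codon sequence with a provenance tag.

    ``representation`` records whether the codons came from a bit-string
    genome (``"binary-derived"``) or a real-valued vector (``"real-derived"``).
    """

    codons: tuple[int, ...]
    representation: str = "binary-derived"

    def __post_init__(self) -> None:
        codons = tuple(int(c) for c in self.codons)
        object.__setattr__(self, "codons", codons)
        if any(not (0 <= c <= 255) for c in codons):
            raise ValueError("codons must lie in [0, 255]")


def _tokenize_body(body: str, lineno: int) -> tuple[Symbol, ...]:
    symbols: list[Symbol] = []
    for tok in _TOKEN_RE.findall(body):
        if tok.startswith("<") and tok.endswith(">"):
            symbols.append((NT, tok))
        elif (tok[0] == '"' and tok[-1] == '"') or (tok[0] == "'" and tok[-1] == "'"):
            text = tok[1:-1]
            if text:  # the empty terminal "" contributes nothing
                symbols.append((T, text))
        else:
            symbols.append((T, tok))
    return tuple(symbols)


def load_grammar(bnf_text: str, start: Optional[str] = None) -> Grammar:
    """Parse BNF text (``<nt> ::= alt | alt``; ``#`` comments).

    A rule may span lines: text before the next ``::=`` line belongs to the
    current rule.  The start symbol defaults to ``<architecture>`` when that
    rule exists, else to the first rule defined.
    """
    if not bnf_text.strip():
        raise GrammarError("empty grammar text")
    rules: list[tuple[str, str, int]] = []  # (lhs, body text, line number)
    for lineno, raw in enumerate(bnf_text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        if "::=" in line:
            lhs, body = line.split("::=", 1)
            lhs = lhs.strip()
            if not (lhs.startswith("<") and lhs.endswith(">")):
                raise GrammarError(f"line {lineno}: bad rule head {lhs!r}")
            rules.append((lhs, body, lineno))
        else:
            if not rules:
                raise GrammarError(f"line {lineno}: text before first rule")
            lhs, body, first = rules[-1]
            rules[-1] = (lhs, body + " " + line, first)

    productions: dict[str, tuple[tuple[Symbol, ...], ...]] = {}
    for lhs, body, lineno in rules:
        if body.strip() == "":
            raise GrammarError(f"line {lineno}: rule {lhs} has no productions")
        alts = tuple(
            _tokenize_body(alt, lineno) for alt in body.split("|")
        )
        if lhs in productions:
            raise GrammarError(f"line {lineno}: rule {lhs} defined twice")
        productions[lhs] = alts

    for lhs, alts in productions.items():
        for alt in alts:
            for kind, value in alt:
                if kind == NT and value not in productions:
                    raise GrammarError(
                        f"nonterminal {value} referenced in {lhs} is not defined"
                    )
    if start is None:
        start = "<architecture>" if "<architecture>" in productions else next(
            iter(productions)
        )
    if start not in productions:
        raise GrammarError(f"start symbol {start} is not defined")
    return Grammar(start=start, productions=productions)


def default_grammar() -> Grammar:
    """The shipped SNN-topology grammar (start symbol ``<architecture>``)."""
    text = (
        resources.files("gesnn").joinpath("grammars/snn.bnf").read_text("utf-8")
    )
    return load_grammar(text)


def map_genotype(
    genotype: Union[Genotype, Sequence[int], np.ndarray],
    grammar: Grammar,
) -> Optional[str]:
    """Depth-first GE mapping of a codon sequence to a terminal word.

    Returns the word, or :data:`INVALID` (``None``) when the codons are
    exhausted with nonterminals remaining.  Pure function of its arguments.
    """
    codons = genotype.codons if isinstance(genotype, Genotype) else genotype
    out: list[str] = []
    stack: list[Symbol] = [(NT, grammar.start)]
    i = 0
    n = len(codons)
    while stack:
        kind, value = stack.pop()
        if kind == T:
            out.append(value)
            continue
        alts = grammar.productions[value]
        if len(alts) > 1:
            if i >= n:
                return INVALID
            choice = int(codons[i]) % len(alts)
            i += 1
        else:
            choice = 0
        stack.extend(reversed(alts[choice]))
    return "".join(out)


def _parse_config(config: str, block_idx: int) -> tuple[int, float, float]:
    fields = config.split("@")
    if len(fields) != 3:
        raise WordParseError(
            f"block {block_idx}: synapse config {config!r} does not have "
            "three @-separated fields"
        )
    try:
        ident = int(fields[0])
        weight = round(float(fields[1]), 2)
        delay = round(float(fields[2]), 2)
    except ValueError as exc:
        raise WordParseError(
            f"block {block_idx}: malformed synapse config {config!r}"
        ) from exc
    return ident, weight, delay


def parse_word(word: str, n_inputs: int) -> NetworkTopology:
    """Convert a dialect word into a :class:`NetworkTopology`.

    Neuron identifiers are reduced modulo ``n_inputs``; delays are clamped
    into [0.01, 19.99].  Each ``{``-terminated block must carry at least one
    input-synapse configuration plus the output-synapse configuration.
    """
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    if "{" not in word:
        raise WordParseError("word contains no hidden-neuron block ('{')")
    blocks = word.split("{")
    if blocks[-1] != "":
        raise WordParseError("word does not end with '{'")
    hidden: list[HiddenNeuronSpec] = []
    for b, block in enumerate(blocks[:-1]):
        configs = block.split("(")
        if len(configs) < 2:
            raise WordParseError(
                f"block {b}: needs at least one input synapse and one "
                "output synapse"
            )
        input_syn: list[SynapseSpec] = []
        for config in configs[:-1]:
            ident, weight, delay = _parse_config(config, b)
            delay = min(max(delay, DELAY_MIN), DELAY_MAX)
            input_syn.append(
                SynapseSpec(presyn_id=ident % n_inputs, weight=weight, delay=delay)
            )
        _, weight, delay = _parse_config(configs[-1], b)
        delay = min(max(delay, DELAY_MIN), DELAY_MAX)
        hidden.append(
            HiddenNeuronSpec(
                input_synapses=tuple(input_syn),
                output_synapse=SynapseSpec(presyn_id=0, weight=weight, delay=delay),
            )
        )
    return NetworkTopology(n_inputs=n_inputs, hidden=tuple(hidden))


def serialize_topology(topology: NetworkTopology) -> str:
    """Render a topology as a dialect word (2-decimal weights and delays).

    Inverse of :func:`parse_word` for topologies whose weights and delays are
    already rounded to 2 decimals.
    """
    parts: list[str] = []
    for h in topology.hidden:
        for s in h.input_synapses:
            parts.append(f"{s.presyn_id}@{s.weight:.2f}@{s.delay:.2f}(")
        o = h.output_synapse
        parts.append(f"0@{o.weight:.2f}@{o.delay:.2f}{{")
    return "".join(parts)
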