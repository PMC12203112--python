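"""Gene-protein-reaction (GPR) rules as explicit boolean trees.

A GPR rule links a reaction to the genes whose products catalyse it:
``and`` expresses a complex (all subunits required), ``or`` expresses
isozymes (any one suffices). Expression data are pushed through the tree
with AND -> min and OR -> sum, yielding a nonnegative activity score per
reaction (see :mod:`imic.expression`).

Parsing of the boolean strings found in SBML/fbc files is delegated to
COBRApy's battle-tested grammar; the tree kept here is a small immutable
structure that the rest of the package can evaluate and serialise without
carrying cobra objects around.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field
from typing import Iterator

__all__ = ["GprTree", "parse_gpr", "GprParseError"]


class GprParseError(ValueError):
    """Raised when a GPR string cannot be parsed into a boolean tree."""


@dataclass(frozen=True)
class GprTree:
    """Node of a GPR boolean tree.

    ``op`` is one of ``"gene"`` (leaf), ``"and"`` or ``"or"``. Interior
    nodes hold >= 2 children (associativity is flattened on construction).
    """

    op: str
    gene: str | None = None
    children: tuple["GprTree", ...] = field(default=())

    def __post_init__(self) -> None:
        if self.op == "gene":
            if not self.gene:
                raise ValueError("leaf node requires a gene id")
        elif self.op in ("and", "or"):
            if len(self.children) < 2:
                raise ValueError(f"'{self.op}' node requires >=2 children")
        else:
            raise ValueError(f"unknown GPR node op: {self.op!r}")

    # -- constructors -------------------------------------------------
    @staticmethod
    def leaf(gene: str) -> "GprTree":
        return GprTree("gene", gene=gene)

    @staticmethod
    def all_of(*children: "GprTree") -> "GprTree":
        return GprTree("and", children=_flatten("and", children))

    @staticmethod
    def any_of(*children: "GprTree") -> "GprTree":
        return GprTree("or", children=_flatten("or", children))

    # -- queries ------------------------------------------------------
    def genes(self) -> set[str]:
        return set(self.iter_genes())

    def iter_genes(self) -> Iterator[str]:
        if self.op == "gene":
            yield self.gene  # type: ignore[misc]
        else:
            for child in self.children:
                yield from child.iter_genes()

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        sep = f" {self.op} "
        parts = []
        for child in self.children:
            s = child.to_string()
            if child.op != "gene":
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _flatten(op: str, children: tuple[GprTree, ...]) -> tuple[GprTree, ...]:
    out: list[GprTree] = []
    for child in children:
        if child.op == op:
            out.extend(child.children)
        else:
            out.append(child)
    return tuple(out)


def parse_gpr(rule: str) -> GprTree | None:
    """Parse a boolean GPR string into a :class:`GprTree`.

    Returns ``None`` for an empty rule. Raises :class:`GprParseError` if
    the string is not a valid boolean gene expression.
    """
    if rule is None or not rule.strip():
        return None
    # cobra normalises odd gene identifiers before handing the string to
    # Python's ast, which a hand-rolled grammar would get wrong.
    from cobra.core.gene import GPR

    try:
        gpr = GPR.from_string(rule)
    except (SyntaxError, TypeError, ValueError) as exc:  # pragma: no cover
        raise GprParseError(f"unparseable GPR string {rule!r}: {exc}") from exc
    if gpr.body is None:
        if gpr.genes:
            raise GprParseError(f"unparseable GPR string {rule!r}")
        return None
    try:
        return _from_ast(gpr.body)
    except GprParseError:
        raise
    except Exception as exc:
        raise GprParseError(f"unparseable GPR string {rule!r}: {exc}") from exc


def from_cobra_gpr(gpr) -> GprTree | None:
    """Convert a ``cobra.core.gene.GPR`` object into a :class:`GprTree`."""
    if gpr is None or gpr.body is None:
        return None
    return _from_ast(gpr.body)


def _from_ast(node) -> GprTree:
    if isinstance(node, ast.Expression):
        return _from_ast(node.body)
    if isinstance(node, ast.Name):
        return GprTree.leaf(node.id)
    if isinstance(node, ast.BoolOp):
        children = tuple(_from_ast(v) for v in node.values)
        if isinstance(node.op, ast.And):
            return GprTree.all_of(*children)
        if isinstance(node.op, ast.Or):
            return GprTree.any_of(*children)
    raise GprParseError(f"unsupported GPR syntax node: {ast.dump(node)}")
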