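"""Exception hierarchy shared by all treeside modules."""

from __future__ import annotations

from typing import Optional, Sequence


class TreesideError(Exception):
    """Base class for all errors raised by treeside."""


class NewickParseError(TreesideError):
    """Malformed Newick text; carries the character offset of the failure."""

    def __init__(self, message: str, offset: Optional[int] = None):
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)
        self.offset = offset


class ValidationError(TreesideError):
    """Structurally well-formed input that violates a semantic precondition."""


class LeafSetMismatchError(ValidationError):
    """Two trees offered for comparison do not carry identical leaf labels."""

    def __init__(self, only_first: Sequence[str], only_second: Sequence[str]):
        self.only_first = tuple(sorted(only_first))
        self.only_second = tuple(sorted(only_second))
        super().__init__(
            "leaf sets differ: only in first tree: "
            f"{list(self.only_first)}; only in second tree: {list(self.only_second)}"
        )


class StructureError(TreesideError):
    """An operation referenced a node or edge that is not part of the tree."""
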