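"""Tiny lme4-style formula parser for pipeline configs.

Understands strings of the form::

    response ~ term1 + term2 + (1|group)

i.e. a response name, fixed categorical terms joined by ``+``, and at most one
random-intercept term ``(1|group)``.  This is all the model grammar the
standardization pipeline uses; anything fancier (interactions, nesting,
random slopes) is rejected loudly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass


class FormulaError(ValueError):
    """Raised on a formula the pipeline grammar does not cover."""


_RANDOM_RE = re.compile(r"^\(\s*1\s*\|\s*([A-Za-z_][A-Za-z0-9_]*)\s*\)$")
_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


@dataclass(frozen=True)
class ParsedFormula:
    response: str
    fixed_terms: tuple
    random_group: str | None

    def __str__(self) -> str:
        rhs = list(self.fixed_terms)
        if self.random_group is not None:
            rhs.append(f"(1|{self.random_group})")
        return f"{self.response} ~ {' + '.join(rhs) if rhs else '1'}"


def parse_formula(formula: str) -> ParsedFormula:
    """Parse ``response ~ a + b + (1|g)`` into its components."""
    if formula.count("~") != 1:
        raise FormulaError(f"formula needs exactly one '~': {formula!r}")
    lhs, rhs = (side.strip() for side in formula.split("~"))
    if not _NAME_RE.match(lhs):
        raise FormulaError(f"invalid response name: {lhs!r}")
    fixed = []
    random_group = None
    for raw in rhs.split("+"):
        tok = raw.strip()
        if not tok or tok == "1":
            continue
        m = _RANDOM_RE.match(tok)
        if m:
            if random_group is not None:
                raise FormulaError("at most one random intercept term allowed")
            random_group = m.group(1)
        elif _NAME_RE.match(tok):
            fixed.append(tok)
        else:
            raise FormulaError(f"unsupported term: {tok!r}")
    return ParsedFormula(lhs, tuple(fixed), random_group)
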