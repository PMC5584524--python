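"""Real-time consistency checks on an expert's hybrid summaries.

Four rules are applied to every candidate answer.  Two are hard errors that
block the answer outright (total probability must be 100%; L < M < H within
the scale); two are soft warnings that prompt the expert to confirm rather
than block (a uniform distribution contradicts the premise that the mode
carries the most probability; stated limits spanning the entire scale
suggest complete uncertainty).  Skewed but self-consistent answers are never
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Real

import numpy as np

from .hybrid import bin_edges
from .quantities import QuantityDefinition

RULE_IDS = ("TOTAL_PROB", "ORDERING", "NON_UNIFORM", "NOT_FULL_RANGE")
ERROR_RULES = frozenset({"TOTAL_PROB", "ORDERING"})
WARNING_RULES = frozenset({"NON_UNIFORM", "NOT_FULL_RANGE"})

_DENSITY_TOL = 1e-9


class InputError(TypeError):
    """Raised when a candidate answer is not numeric."""


@dataclass(frozen=True)
class CheckResult:
    rule_id: str
    severity: str  # "error" | "warning"
    passed: bool
    message: str


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of the four consistency rules on one candidate answer."""

    checks: tuple[CheckResult, ...]

    def __post_init__(self) -> None:
        ids = [c.rule_id for c in self.checks]
        if sorted(ids) != sorted(RULE_IDS):
            raise ValueError(f"report must contain exactly the rules {RULE_IDS}, got {ids}")

    @property
    def overall_valid(self) -> bool:
        """True iff no failed check has error severity (warnings allowed)."""
        return not any(c.severity == "error" and not c.passed for c in self.checks)

    @property
    def failed_warnings(self) -> frozenset[str]:
        return frozenset(
            c.rule_id for c in self.checks if c.severity == "warning" and not c.passed
        )

    @property
    def failed_errors(self) -> frozenset[str]:
        return frozenset(
            c.rule_id for c in self.checks if c.severity == "error" and not c.passed
        )

    def __getitem__(self, rule_id: str) -> CheckResult:
        for c in self.checks:
            if c.rule_id == rule_id:
                return c
        raise KeyError(rule_id)

    def to_json(self) -> dict:
        return {
            "overall_valid": self.overall_valid,
            "checks": [
                {
                    "rule_id": c.rule_id,
                    "severity": c.severity,
                    "passed": bool(c.passed),
                    "message": c.message,
                }
                for c in self.checks
            ],
        }

    @classmethod
    def from_json(cls, d: dict) -> "ValidationReport":
        return cls(
            checks=tuple(
                CheckResult(c["rule_id"], c["severity"], c["passed"], c["message"])
                for c in d["checks"]
            )
        )


def _require_numeric(name: str, value) -> float:
    if isinstance(value, bool) or not isinstance(value, Real):
        raise InputError(f"{name} must be numeric, got {value!r}")
    return float(value)


def validate(
    L, M, H, p, quantity: QuantityDefinition, *, prob_tol: float = 1e-9
) -> ValidationReport:
    """Run the four consistency rules on a raw candidate answer.

    ``L``, ``M``, ``H`` are on the quantity scale and ``p`` holds the four
    interval probabilities as fractions.  The report carries failures; only
    non-numeric input raises.
    """
    L = _require_numeric("L", L)
    M = _require_numeric("M", M)
    H = _require_numeric("H", H)
    p = tuple(_require_numeric(f"p{i + 1}", v) for i, v in enumerate(p))
    if len(p) != 4:
        raise InputError(f"expected 4 interval probabilities, got {len(p)}")

    checks = []

    total = sum(p)
    ok_total = abs(total - 1.0) <= prob_tol and all(x >= 0 for x in p)
    checks.append(
        CheckResult(
            "TOTAL_PROB",
            "error",
            ok_total,
            "100% of the probability is allocated to the histogram"
            if ok_total
            else f"probabilities allocate {100 * total:.6g}% of probability, not 100%",
        )
    )

    ok_order = (
        quantity.scale_min <= L < M < H <= quantity.scale_max
    )
    if ok_order:
        msg = "L < M < H and within the scale"
    elif not L < M:
        msg = f"L < M violated (L={L:g}, M={M:g})"
    elif not M < H:
        msg = f"M < H violated (M={M:g}, H={H:g})"
    else:
        msg = (
            f"limits outside the scale [{quantity.scale_min:g}, {quantity.scale_max:g}]"
            f" (L={L:g}, H={H:g})"
        )
    checks.append(CheckResult("ORDERING", "error", ok_order, msg))

    # Uniformity is judged on density (probability / width): the four bins
    # have unequal widths, so equal raw probabilities are not a uniform
    # belief.  A non-uniform answer has strictly higher density in at least
    # one bin adjacent to M than in its outer neighbour.
    if ok_order and ok_total:
        d = np.asarray(p) / np.diff(bin_edges(L, M, H))
        non_uniform = bool(d[1] > d[0] + _DENSITY_TOL) or bool(d[2] > d[3] + _DENSITY_TOL)
        msg = (
            "probability rises toward the mode"
            if non_uniform
            else "the answer is a uniform (or mode-avoiding) distribution; "
            "by definition M should carry more probability"
        )
    else:
        non_uniform = True  # cannot be judged; only errors block
        msg = "not assessed (ordering or total-probability error)"
    checks.append(CheckResult("NON_UNIFORM", "warning", non_uniform, msg))

    full_range = L <= quantity.scale_min and H >= quantity.scale_max
    checks.append(
        CheckResult(
            "NOT_FULL_RANGE",
            "warning",
            not full_range,
            "the extreme values cover the entire range, suggesting complete uncertainty"
            if full_range
            else "stated limits do not span the whole scale",
        )
    )

    return ValidationReport(checks=tuple(checks))


def confirm_warnings(report: ValidationReport, confirmations: set[str] | frozenset[str]):
    """Decide whether a validated answer is accepted.

    Accepted iff no error rule failed and every failed warning rule id is in
    ``confirmations``.  Offering a confirmation for an error-severity rule is
    rejected with an explanatory message.

    Returns
    -------
    (accepted, message) : tuple[bool, str]
    """
    confirmations = frozenset(confirmations)
    bad = confirmations & ERROR_RULES
    if bad:
        return False, (
            f"rules {sorted(bad)} are hard errors and cannot be confirmed away; "
            "correct the answer instead"
        )
    unknown = confirmations - frozenset(RULE_IDS)
    if unknown:
        return False, f"unknown rule ids in confirmations: {sorted(unknown)}"
    if report.failed_errors:
        return False, f"answer has unresolved errors: {sorted(report.failed_errors)}"
    missing = report.failed_warnings - confirmations
    if missing:
        return False, f"warnings require confirmation: {sorted(missing)}"
    return True, "accepted"
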