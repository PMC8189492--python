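"""Decision-tree recommendation of a correction method.

The choice of correction hinges on a handful of study-design questions:
is the analysis exploratory (hypothesis-generating screens tolerate some
false positives in exchange for power) or confirmatory (pre-registered
hypotheses demand strict FWER control); how many tests are in the family;
are the tests dependent; and can any false positives be tolerated at all.

The encoded decision table is an explicit interpretation, versioned here:

1. If false positives cannot be tolerated, control the FWER regardless of
   family size; Holm is the concrete pick (it dominates Bonferroni and is
   valid under arbitrary dependence).
2. Otherwise, a confirmatory analysis with a small family (at most
   ``small_n``, default 300 — "a couple of dozens to a couple of
   hundreds") also stays in the FWER family (Holm).
3. Otherwise (exploratory, or a large family): control the FDR.  With
   dependent tests, use Benjamini–Yekutieli (valid under arbitrary
   dependence; PFP is the pi0-based alternative); with independent tests,
   use Benjamini–Hochberg and report q-values alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Recommendation", "recommend_method", "SMALL_N_DEFAULT"]

SMALL_N_DEFAULT = 300


@dataclass(frozen=True)
class Recommendation:
    """A recommended method with the question/answer path that led to it."""

    method: str
    path: tuple[tuple[str, str], ...] = field(default_factory=tuple)
    caveat: str = ""


def recommend_method(
    exploratory: bool,
    n_tests: int,
    dependent: bool,
    tolerate_false_positives: bool,
    small_n: int = SMALL_N_DEFAULT,
) -> Recommendation:
    """Recommend a correction method from four study-design answers.

    Total over all answer combinations: every combination yields exactly
    one method implemented in this package, and the traversal path is
    reproducible from the answers alone.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be a positive integer")
    path = [
        ("Is the analysis exploratory?", "yes" if exploratory else "no"),
        ("How many tests are in the family?", str(n_tests)),
        ("Are the tests dependent?", "yes" if dependent else "no"),
        (
            "Can false positives be tolerated?",
            "yes" if tolerate_false_positives else "no",
        ),
    ]
    if not tolerate_false_positives:
        return Recommendation(
            method="holm",
            path=tuple(path),
            caveat=(
                "FWER family chosen because no false positives are tolerated; "
                "Holm dominates Bonferroni and needs no dependence assumption. "
                "Hochberg is slightly more powerful if tests are independent "
                "or positively dependent."
            ),
        )
    if not exploratory and n_tests <= small_n:
        return Recommendation(
            method="holm",
            path=tuple(path),
            caveat=(
                f"Confirmatory analysis with a small family (n <= {small_n}): "
                "FWER control is appropriate; Holm chosen within the "
                "Bonferroni/Holm/Hochberg family."
            ),
        )
    if dependent:
        return Recommendation(
            method="by",
            path=tuple(path),
            caveat=(
                "Exploratory or large family with dependent tests: "
                "Benjamini-Yekutieli controls the FDR under arbitrary "
                "dependence; the pi0-based PFP estimate is an alternative."
            ),
        )
    return Recommendation(
        method="bh",
        path=tuple(path),
        caveat=(
            "Exploratory or large family with independent tests: "
            "Benjamini-Hochberg FDR control; report q-values alongside "
            "for a per-test minimum-FDR measure."
        ),
    )
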