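"""Ternary landscape-mosaic classification.

A *landscape mosaic* labels a location by the composition of three land
cover types (conventionally coded as gray levels 1, 2, 3 — e.g.
agriculture, developed, natural) among the pixels of the analysis window.
The composition ``(p1, p2, p3)`` is a point on the 2-simplex and the
classifier is a fixed, deterministic partition of that simplex into
nominal classes; it is defined only when ``p1 + p2 + p3 = 1``, i.e. when
the window contains no gray level outside {1, 2, 3}.

Two partitions are provided:

* **19-class** (coarse): thresholds at 10 %, 60 % and 100 % on each axis.
  Each proportion is graded High (>= 60 %), Medium (10-60 %) or Low
  (< 10 %); at most one axis can be High.  Classes: 3 pure corners
  (one type is 100 %), 12 single-dominant classes (one High axis, the two
  minority axes each Low or Medium), and 4 no-dominant classes (the
  mixed interior), for 19 in all.
* **103-class** (fine): the 10-step ternary subdivision of the simplex
  into 100 small triangles (55 upward, 45 downward) plus the 3 pure
  corners, for 103 in all.

Code numbering is canonical to this package (corners first, then
dominant/edge classes, then interior; triangles in row-major order) and
stable across releases.  Compositions on a partition boundary are
assigned deterministically (thresholds are closed on the left, lattice
points fall to the adjacent upward triangle), so the classifiers are
total and single-valued on the valid simplex.
"""

from __future__ import annotations

import math

_EPS = 1e-9


def composition_is_valid(p1: float, p2: float, p3: float) -> bool:
    """True when (p1, p2, p3) is a point of the ternary simplex."""
    if min(p1, p2, p3) < -_EPS:
        return False
    return math.isclose(p1 + p2 + p3, 1.0, abs_tol=_EPS)


def _grade(p: float) -> str:
    """High / Medium / Low grading with closed-left thresholds."""
    if p >= 0.6 - _EPS:
        return "H"
    if p >= 0.1 - _EPS:
        return "M"
    return "L"


def classify_mosaic19(p1: float, p2: float, p3: float) -> int | None:
    """Coarse 19-class landscape-mosaic code, or None off the simplex."""
    if not composition_is_valid(p1, p2, p3):
        return None
    props = (p1, p2, p3)
    # pure corners: one type is 100 %
    for axis, p in enumerate(props):
        if p >= 1.0 - _EPS:
            return axis + 1  # codes 1..3
    grades = [_grade(p) for p in props]
    if "H" in grades:  # at most one axis can reach 60 %
        dom = grades.index("H")
        others = [grades[a] for a in range(3) if a != dom]
        combo = {"LL": 0, "ML": 1, "LM": 2, "MM": 3}["".join(others)]
        return 4 + 4 * dom + combo  # codes 4..15
    if "L" in grades:  # two mediums and one low
        return 16 + grades.index("L")  # codes 16..18
    return 19  # three mediums: the mixed interior


def classify_mosaic103(p1: float, p2: float, p3: float) -> int | None:
    """Fine 103-class landscape-mosaic code, or None off the simplex.

    Codes 1..55 are the upward triangles (i + j <= 9, row-major in the
    decile indices of p1 and p2), 56..100 the downward triangles
    (i + j <= 8), and 101..103 the pure corners.
    """
    if not composition_is_valid(p1, p2, p3):
        return None
    props = (p1, p2, p3)
    for axis, p in enumerate(props):
        if p >= 1.0 - _EPS:
            return 101 + axis
    i = int(math.floor(10.0 * p1 + _EPS))
    j = int(math.floor(10.0 * p2 + _EPS))
    k = int(math.floor(10.0 * p3 + _EPS))
    s = i + j + k  # 9: upward triangle, 8: downward, 10: lattice point
    if s == 10:
        # lattice point shared by several triangles: assign to the upward
        # triangle below it (decrement p3's index, else p2's)
        if k >= 1:
            k -= 1
        else:
            j -= 1
        s = 9
    if s == 9:
        return 1 + _upward_index(i, j)
    return 56 + _downward_index(i, j)


def _upward_index(i: int, j: int) -> int:
    """Row-major rank of upward triangle (i, j), i + j <= 9."""
    # rows i = 0..9, row i has 10 - i entries
    return sum(10 - a for a in range(i)) + j


def _downward_index(i: int, j: int) -> int:
    """Row-major rank of downward triangle (i, j), i + j <= 8."""
    return sum(9 - a for a in range(i)) + j


def classify_mosaic(p1: float, p2: float, p3: float, variant: int = 19) -> int | None:
    """Dispatch to the 19- or 103-class partition."""
    if variant == 19:
        return classify_mosaic19(p1, p2, p3)
    if variant == 103:
        return classify_mosaic103(p1, p2, p3)
    raise ValueError(f"variant must be 19 or 103, got {variant}")


# -- legend -----------------------------------------------------------------

_COMBO_DESC = {
    "LL": "both minority types below 10 %",
    "ML": "first minority type 10-60 %, second below 10 %",
    "LM": "first minority type below 10 %, second 10-60 %",
    "MM": "both minority types 10-60 %",
}


def legend(variant: int = 19) -> list[tuple[int, str]]:
    """(code, description) pairs for the requested partition."""
    if variant == 19:
        rows = [(a + 1, f"pure type {a + 1} (100 %)") for a in range(3)]
        for dom in range(3):
            minors = [a + 1 for a in range(3) if a != dom]
            for c, combo in enumerate(("LL", "ML", "LM", "MM")):
                rows.append(
                    (
                        4 + 4 * dom + c,
                        f"type {dom + 1} dominant (>= 60 %); minority types "
                        f"{minors[0]} and {minors[1]}: {_COMBO_DESC[combo]}",
                    )
                )
        for low in range(3):
            others = [a + 1 for a in range(3) if a != low]
            rows.append(
                (
                    16 + low,
                    f"no dominant type; types {others[0]} and {others[1]} "
                    f"10-60 %, type {low + 1} below 10 %",
                )
            )
        rows.append((19, "no dominant type; all three types 10-60 %"))
        return rows
    if variant == 103:
        rows = []
        for i in range(10):
            for j in range(10 - i):
                rows.append(
                    (
                        1 + _upward_index(i, j),
                        f"upward triangle: p1 in [{i / 10:.1f},{(i + 1) / 10:.1f}], "
                        f"p2 in [{j / 10:.1f},{(j + 1) / 10:.1f}]",
                    )
                )
        for i in range(9):
            for j in range(9 - i):
                rows.append(
                    (
                        56 + _downward_index(i, j),
                        f"downward triangle: p1 in [{i / 10:.1f},{(i + 1) / 10:.1f}], "
                        f"p2 in [{j / 10:.1f},{(j + 1) / 10:.1f}]",
                    )
                )
        rows.extend((101 + a, f"pure type {a + 1} (100 %)") for a in range(3))
        return rows
    raise ValueError(f"variant must be 19 or 103, got {variant}")


def write_legend(path, variant: int = 19) -> None:
    """Write a plain-text class legend (code<TAB>description per line)."""
    lines = [f"{code}\t{desc}" for code, desc in legend(variant)]
    with open(path, "w") as fh:
        fh.write(f"# landscape mosaic legend, {variant}-class partition\n")
        fh.write("\n".join(lines) + "\n")
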