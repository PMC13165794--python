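"""Definition of the 789 m urban test course.

The course is a closed loop through a suburban street network, divided into
13 sections with distinct terrain (car park, tilted pavements, downhill
streets, a steep climb, a final sprint).  Each section carries the cohort
mean +/- SD of speed and seat centre-of-pressure position observed on it;
these per-section statistics drive the synthetic-run generator and are the
reference values for the noise-free round-trip checks.

Turns between sections (90-degree street corners) are recorded so that the
generator can emit yaw-rate episodes at the matching distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CourseSection",
    "CourseDefinition",
    "DEFAULT_SECTIONS",
    "DEFAULT_TURNS",
    "build_course",
]


@dataclass(frozen=True)
class CourseSection:
    """One leg of the course with its summary statistics.

    Distances in metres, speeds in m/s, COP coordinates in mm from the mat
    centre (+x right, +y forward; negative COPy means rearward of centre).
    """

    index: int
    start_distance: float
    length: float
    v_mean: float
    v_sd: float
    copx_mean: float
    copx_sd: float
    copy_mean: float
    copy_sd: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"section {self.index}: length must be > 0")
        if self.v_mean <= 0:
            raise ValueError(f"section {self.index}: v_mean must be > 0")
        if self.v_sd < 0 or self.copx_sd < 0 or self.copy_sd < 0:
            raise ValueError(f"section {self.index}: SDs must be >= 0")

    @property
    def end_distance(self) -> float:
        return self.start_distance + self.length


# The 13 legs of the default course: (start, length, v_mean, v_sd,
# copx_mean, copx_sd, copy_mean, copy_sd, label).
DEFAULT_SECTIONS: tuple[CourseSection, ...] = tuple(
    CourseSection(i + 1, *row)
    for i, row in enumerate(
        [
            (0.0, 47.0, 0.80, 0.23, -1.56, 6.02, -17.45, 7.94, "car park (start)"),
            (47.0, 124.0, 1.02, 0.25, -4.32, 7.59, -18.35, 8.03, "tilted pavement"),
            (171.0, 99.0, 1.26, 0.36, -3.79, 6.61, -17.64, 7.99, "street, downhill"),
            (270.0, 55.0, 1.43, 0.37, -1.52, 7.44, -17.35, 7.66, "street, downhill (end)"),
            (325.0, 39.0, 1.04, 0.23, -4.21, 6.79, -20.83, 7.27, "narrow pavement"),
            (364.0, 43.0, 1.05, 0.22, 2.35, 7.64, -23.83, 7.26, "street, no pavement"),
            (407.0, 74.0, 1.40, 0.40, 5.58, 9.17, -20.82, 8.61, "lane, flat"),
            (481.0, 40.0, 1.28, 0.43, 4.05, 12.29, -21.88, 9.51, "lane after obstacle"),
            (521.0, 50.0, 0.95, 0.25, 3.47, 8.26, -17.43, 15.51, "lane, steep uphill"),
            (571.0, 98.0, 1.41, 0.32, -1.80, 7.27, -19.00, 8.19, "road, downhill"),
            (669.0, 30.0, 1.32, 0.23, -4.10, 7.29, -20.01, 7.93, "tilted pavement"),
            (699.0, 48.0, 1.29, 0.24, -2.04, 8.02, -21.33, 7.94, "pavement"),
            (747.0, 42.0, 1.81, 0.64, 1.93, 9.03, -19.80, 8.10, "car park (sprint)"),
        ]
    )
)

# Street-corner turns at section boundaries: {boundary distance m: signed
# heading change in degrees, positive = counter-clockwise (left turn)}.
# The default loop is driven clockwise, so most turns are right turns.
DEFAULT_TURNS: dict[float, float] = {
    47.0: -90.0,   # car park -> first street, right
    171.0: -90.0,  # -> downhill street, right
    325.0: -90.0,  # -> narrow pavement, right
    364.0: -90.0,  # -> no-pavement street, right
    407.0: 90.0,   # -> lane, left
    571.0: -90.0,  # lane -> downhill road, right
    669.0: -90.0,  # -> pavement, right
    747.0: -90.0,  # -> car park, right
}


@dataclass(frozen=True)
class CourseDefinition:
    """A contiguous sequence of sections starting at distance 0."""

    sections: tuple[CourseSection, ...]
    turns: dict[float, float] = field(default_factory=dict)

    @property
    def n_sections(self) -> int:
        return len(self.sections)

    @property
    def total_length(self) -> float:
        return self.sections[-1].end_distance

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative boundaries, length n_sections + 1, starting at 0."""
        return np.concatenate(
            ([self.sections[0].start_distance], [s.end_distance for s in self.sections])
        )

    def section_of(self, dist: float) -> CourseSection:
        idx = int(np.searchsorted(self.boundaries, dist, side="right")) - 1
        idx = min(max(idx, 0), self.n_sections - 1)
        return self.sections[idx]

    def means(self, parameter: str) -> np.ndarray:
        return np.array([getattr(s, f"{parameter}_mean") for s in self.sections])

    def sds(self, parameter: str) -> np.ndarray:
        return np.array([getattr(s, f"{parameter}_sd") for s in self.sections])


def build_course(
    section_table: list[CourseSection] | None = None,
    turns: dict[float, float] | None = None,
) -> CourseDefinition:
    """Build a course from a section table, validating contiguity.

    With no arguments, returns the default 13-section, 789 m course.
    Sections must be contiguous: each section starts where the previous one
    ends, and the first starts at 0.

    Raises
    ------
    ValueError
        If the sections are not contiguous (the message names the distance
        at which the gap or overlap occurs).
    """
    if section_table is None:
        return CourseDefinition(DEFAULT_SECTIONS, dict(DEFAULT_TURNS))
    sections = tuple(sorted(section_table, key=lambda s: s.start_distance))
    if not sections:
        raise ValueError("course needs at least one section")
    if sections[0].start_distance != 0:
        raise ValueError("first section must start at distance 0")
    for prev, nxt in zip(sections, sections[1:]):
        if not np.isclose(nxt.start_distance, prev.end_distance, atol=1e-9):
            raise ValueError(f"gap at {prev.end_distance:g}")
    if turns is None:
        turns = {}
    boundaries = {s.end_distance for s in sections[:-1]}
    unknown = set(turns) - boundaries
    if unknown:
        raise ValueError(f"turns at non-boundary distances: {sorted(unknown)}")
    return CourseDefinition(sections, dict(turns))
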