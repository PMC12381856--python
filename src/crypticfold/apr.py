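"""Aggregation-prone regions, their overlap with unfolding-exposed
residues, and mutation-level surface-hydrophobicity accounting.

An aggregation-score profile (one dimensionless score per residue, as
produced by sequence/structure aggregation predictors) is segmented
into aggregation-prone regions (APRs): maximal runs of consecutive
residues scoring strictly above a threshold (default 0.25).  A *cryptic*
APR is an APR that is mostly buried in the native state but gains newly
exposed residues during unfolding — the structural signature of
aggregation triggered from a partially unfolded intermediate rather
than from the native surface.

Mutation strings such as "E20S + F80R + C128F" are parsed, located on
the native surface via rASA, and scored for the change in summed
surface hydrophobicity on min-max-normalised residue scales.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .tables import AMINO_ACIDS, HYDROPHOBICITY_SCALES, normalized_scale

APR_THRESHOLD = 0.25
EXPOSURE_THRESHOLD = 0.25


class APRError(ValueError):
    pass


@dataclass(frozen=True)
class MutationSpec:
    """One point mutation in 1-based sequence numbering."""

    wild_type: str
    position: int
    mutant: str

    def __str__(self) -> str:
        return f"{self.wild_type}{self.position}{self.mutant}"


@dataclass
class APRSegment:
    """A contiguous aggregation-prone region, 1-based inclusive bounds."""

    start: int
    end: int
    peak_score: float
    mean_score: float

    def residues(self) -> set:
        return set(range(self.start, self.end + 1))

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class OverlapReport:
    n_newly_exposed: int
    n_newly_exposed_in_apr: int
    fraction_pct: float | None  # None (undefined) for an empty exposed set
    cryptic_aprs: list = field(default_factory=list)
    undefined: bool = False

    def as_dict(self) -> dict:
        return {
            "n_newly_exposed": self.n_newly_exposed,
            "n_newly_exposed_in_apr": self.n_newly_exposed_in_apr,
            "fraction_pct": self.fraction_pct,
            "undefined": self.undefined,
            "cryptic_aprs": [
                {"start": s.start, "end": s.end,
                 "peak_score": s.peak_score, "mean_score": s.mean_score}
                for s in self.cryptic_aprs
            ],
        }


_MUT_RE = re.compile(r"^([A-Za-z])\s*(\d+)\s*([A-Za-z])$")


def parse_mutations(spec: str, sequence: str | None = None) -> list[MutationSpec]:
    """Parse a '+'-separated mutation string.

    Tokens follow the letter-digits-letter pattern, tolerating stray
    internal whitespace (as appears in some printed tables, e.g.
    "D166 K").  When ``sequence`` is given, each wild-type letter is
    validated against the 1-based sequence position and mismatches fail
    loudly.  An empty string yields an empty list.
    """
    if spec is None or not spec.strip():
        return []
    out = []
    for token in spec.split("+"):
        token = token.strip()
        m = _MUT_RE.match(token)
        if not m:
            raise APRError(f"malformed mutation token {token!r}")
        wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
        if wt not in AMINO_ACIDS or mut not in AMINO_ACIDS:
            raise APRError(f"unknown amino-acid letter in token {token!r}")
        if sequence is not None:
            if not (1 <= pos <= len(sequence)):
                raise APRError(f"position {pos} outside the sequence (1-{len(sequence)})")
            if sequence[pos - 1].upper() != wt:
                raise APRError(
                    f"wild-type mismatch at position {pos}: "
                    f"sequence has {sequence[pos - 1]}, mutation says {wt}")
        out.append(MutationSpec(wt, pos, mut))
    return out


def format_mutations(mutations: list[MutationSpec]) -> str:
    """Canonical ' + '-joined mutation string (round-trips with parsing)."""
    return " + ".join(str(m) for m in mutations)


def apply_mutations(sequence: str, mutations: list[MutationSpec]) -> str:
    """Return the mutant sequence (validates wild-type letters)."""
    seq = list(sequence)
    for m in mutations:
        if seq[m.position - 1].upper() != m.wild_type:
            raise APRError(f"wild-type mismatch applying {m}")
        seq[m.position - 1] = m.mutant
    return "".join(seq)


def segment_aprs(scores, threshold: float = APR_THRESHOLD,
                 min_length: int = 1) -> list[APRSegment]:
    """Maximal runs of residues scoring strictly above the threshold.

    Runs shorter than ``min_length`` are discarded; segments are
    returned sorted by start position, 1-based inclusive.
    """
    segments = []
    start = None
    scores = list(scores)
    for i, s in enumerate(scores, start=1):
        if s != s or s in (float("inf"), float("-inf")):
            raise APRError(f"non-finite score at residue {i}")
        if s > threshold:
            if start is None:
                start = i
        elif start is not None:
            segments.append((start, i - 1))
            start = None
    if start is not None:
        segments.append((start, len(scores)))
    out = []
    for a, b in segments:
        if b - a + 1 >= min_length:
            run = scores[a - 1:b]
            out.append(APRSegment(a, b, peak_score=max(run),
                                  mean_score=sum(run) / len(run)))
    return out


def overlap_exposed_aprs(newly_exposed, segments) -> OverlapReport:
    """Fraction of newly exposed residues lying inside any APR.

    An empty exposed set makes the fraction undefined (flagged), never
    zero.
    """
    exposed = set(int(i) for i in newly_exposed)
    apr_union = set()
    for seg in segments:
        apr_union |= seg.residues()
    n_in = len(exposed & apr_union)
    if not exposed:
        return OverlapReport(0, 0, None, undefined=True)
    return OverlapReport(
        n_newly_exposed=len(exposed),
        n_newly_exposed_in_apr=n_in,
        fraction_pct=100.0 * n_in / len(exposed),
    )


def flag_cryptic_aprs(
    segments,
    newly_exposed,
    native_rasa,
    min_hits: int = 2,
    threshold: float = EXPOSURE_THRESHOLD,
) -> list[APRSegment]:
    """APRs that are natively buried yet gain exposure during unfolding.

    A segment is cryptic iff it contains at least ``min_hits`` newly
    exposed residues and the majority of its residues are buried
    (rASA < threshold) in the native state.
    """
    exposed = set(int(i) for i in newly_exposed)
    out = []
    for seg in segments:
        res = sorted(seg.residues())
        hits = len(exposed & set(res))
        n_buried = sum(1 for r in res if native_rasa[r - 1] < threshold)
        if hits >= min_hits and n_buried > len(res) / 2:
            out.append(seg)
    return out


def classify_mutation_locations(
    mutations,
    native_rasa,
    threshold: float = EXPOSURE_THRESHOLD,
):
    """Surface/buried call per mutation from native rASA.

    Returns ``(per_mutation, counts)`` where ``per_mutation`` maps the
    mutation string to "surface" (rASA >= threshold) or "buried".
    """
    per = {}
    counts = {"surface": 0, "buried": 0}
    n = len(native_rasa)
    for m in mutations:
        if not (1 <= m.position <= n):
            raise APRError(f"mutation {m} outside the rASA profile (1-{n})")
        loc = "surface" if native_rasa[m.position - 1] >= threshold else "buried"
        per[str(m)] = loc
        counts[loc] += 1
    return per, counts


def surface_hydrophobicity_change(
    sequence: str,
    mutations,
    native_rasa,
    scale: str | dict = "kyte-doolittle",
    threshold: float = EXPOSURE_THRESHOLD,
) -> float:
    """Percent change in summed surface hydrophobicity due to mutations.

    The surface is the set of residues with native rASA >= threshold;
    exposure status is held fixed at the wild-type structure (no mutant
    structure is predicted).  The scale is min-max normalised to [0, 1]
    before summation, and the change is
    100 * (H_mut - H_wt) / H_wt.
    """
    if isinstance(scale, str):
        try:
            raw = HYDROPHOBICITY_SCALES[scale]
        except KeyError as exc:
            raise APRError(f"unknown hydrophobicity scale {scale!r}") from exc
    else:
        raw = scale
    norm = normalized_scale(raw)
    if len(sequence) != len(native_rasa):
        raise APRError("sequence and rASA profile differ in length")
    mutant = apply_mutations(sequence, mutations)
    surface = [i for i, r in enumerate(native_rasa) if r >= threshold]

    def total(seq):
        try:
            return sum(norm[seq[i]] for i in surface)
        except KeyError as exc:
            raise APRError(f"no scale value for residue {exc}") from exc

    h_wt = total(sequence.upper())
    h_mut = total(mutant.upper())
    if h_wt == 0:
        raise APRError("wild-type surface hydrophobicity sum is zero")
    return 100.0 * (h_mut - h_wt) / h_wt
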