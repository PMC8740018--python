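"""Domain types and input handling for censored microbial enumeration data.

Plate-count surveys report each sample either as a concentration
(CFU/g or CFU/ml), as "ND" (not detected, i.e. below the limit of
quantification, LOQ), or as a count of samples falling in a concentration
band such as 10--10^2 CFU/g (semi-quantitative data).  This module defines
the in-memory representation of such datasets, parses the two common table
layouts, derives the LOQ from the plating scheme, and dispatches each
dataset to one of four analysis modes:

========  ==================  ===================
mode      censored (ND) data  data format
========  ==================  ===================
QN_1      no                  quantitative
QN_2      no                  interval (binned)
QN_3      yes                 quantitative
QN_4      yes                 interval (binned)
========  ==================  ===================

All log-scale quantities are base-10 logarithms of CFU/g; a normal model
on that scale is affine-equivalent to one on the natural-log scale, and
base 10 matches both the decade bins of semi-quantitative records and the
"log CFU/g" convention of reported results.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ValidationError",
    "ParseError",
    "FullyCensoredError",
    "PlatingScheme",
    "Observation",
    "EnumerationDataset",
    "MODES",
    "ND_TOKENS",
    "compute_loq",
    "infer_mode",
    "parse_quantitative",
    "parse_interval_counts",
    "censored_fraction",
    "to_fitting_convention",
    "dataset_to_json",
    "dataset_from_json",
    "write_csv",
    "read_csv",
    "load_case",
]

MODES = ("QN_1", "QN_2", "QN_3", "QN_4")

#: accepted spellings (case-insensitive) of the "not detected" marker
ND_TOKENS = frozenset({"nd", "n.d.", "not detected", "not_detected", "<loq"})

_BOUND_TOL = 1e-9  # slack for floating comparisons of log10 bounds


class ValidationError(ValueError):
    """The input data violate a structural requirement."""


class ParseError(ValueError):
    """A record could not be interpreted as a concentration or ND marker."""


class FullyCensoredError(ValidationError):
    """Every observation lies below the LOQ.

    A 100%-censored (presence/absence-like) dataset carries no information
    that identifies both parameters of a lognormal concentration model;
    such data need qualitative-test methods outside this package's scope.
    """


# ---------------------------------------------------------------------------
# plating scheme and LOQ


@dataclass(frozen=True)
class PlatingScheme:
    """Dilution/plating metadata from which the LOQ is derived.

    Parameters
    ----------
    sample_mass : float
        Mass of food sample homogenized, in grams (> 0).
    diluent_volume : float
        Volume of diluent added to the sample, in ml (> 0).
    plated_volume : float
        Volume of the (possibly further diluted) homogenate spread on the
        plate, in ml.  Defaults to the conventional 1 ml.
    extra_dilution_factor : float
        Additional serial-dilution factor beyond the primary homogenate
        (>= 1, dimensionless).
    """

    sample_mass: float
    diluent_volume: float
    plated_volume: float = 1.0
    extra_dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sample_mass", "diluent_volume", "plated_volume",
                     "extra_dilution_factor"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be a positive finite number, got {v!r}")
        if self.extra_dilution_factor < 1:
            raise ValidationError("extra_dilution_factor must be >= 1")


def compute_loq(scheme: PlatingScheme) -> float:
    """Limit of quantification in CFU/g implied by a plating scheme.

    One colony on the plate corresponds to
    ``(sample_mass + diluent_volume) / sample_mass * extra_dilution_factor
    / plated_volume`` CFU per gram of sample; concentrations below that
    cannot be quantified.  The classic 25 g + 225 ml homogenate with 1 ml
    plated gives the ubiquitous LOQ of 10 CFU/g.
    """
    s = scheme
    return ((s.sample_mass + s.diluent_volume) / s.sample_mass
            * s.extra_dilution_factor / s.plated_volume)


# ---------------------------------------------------------------------------
# observations and datasets


@dataclass(frozen=True)
class Observation:
    """One enumeration result on the log10 CFU/g scale.

    ``kind`` is one of ``"exact"`` (a measured concentration),
    ``"left_censored"`` (known only to lie below ``upper``) or
    ``"interval"`` (known only to lie in ``[lower, upper)``).  ``weight``
    is the number of samples sharing the observation.
    """

    kind: str
    value: float | None = None
    lower: float | None = None
    upper: float | None = None
    weight: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("exact", "left_censored", "interval"):
            raise ValidationError(f"unknown observation kind {self.kind!r}")
        if not (isinstance(self.weight, int) and self.weight >= 1):
            raise ValidationError("weight must be an integer >= 1")
        if self.kind == "exact":
            if self.value is None or not math.isfinite(self.value):
                raise ValidationError("exact observation requires a finite value")
        elif self.kind == "left_censored":
            if self.upper is None or not math.isfinite(self.upper):
                raise ValidationError("left_censored observation requires a finite upper bound")
        else:  # interval
            if self.lower is None or self.upper is None:
                raise ValidationError("interval observation requires lower and upper")
            if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
                raise ValidationError("interval bounds must be finite")
            if not self.lower < self.upper:
                raise ValidationError(
                    f"interval requires lower < upper, got [{self.lower}, {self.upper}]")

    # convenience constructors -------------------------------------------------
    @classmethod
    def exact(cls, value: float, weight: int = 1) -> "Observation":
        return cls("exact", value=float(value), weight=weight)

    @classmethod
    def left_censored(cls, upper: float, weight: int = 1) -> "Observation":
        return cls("left_censored", upper=float(upper), weight=weight)

    @classmethod
    def interval(cls, lower: float, upper: float, weight: int = 1) -> "Observation":
        return cls("interval", lower=float(lower), upper=float(upper), weight=weight)


def infer_mode(has_censored: bool, has_interval: bool) -> str:
    """Dispatch a dataset shape to its QN analysis mode."""
    return {(False, False): "QN_1", (False, True): "QN_2",
            (True, False): "QN_3", (True, True): "QN_4"}[(has_censored, has_interval)]


@dataclass(frozen=True)
class EnumerationDataset:
    """A collection of observations plus the LOQ and provenance metadata."""

    observations: tuple[Observation, ...]
    loq: float
    mode: str
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        if not (math.isfinite(self.loq) and self.loq > 0):
            raise ValidationError(f"loq must be positive and finite, got {self.loq!r}")
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.total_weight < 1:
            raise ValidationError("dataset must contain at least one observation")
        lql = math.log10(self.loq)
        for o in self.observations:
            if o.kind == "left_censored" and o.upper > lql + _BOUND_TOL:
                raise ValidationError(
                    "left-censored bound above log10(LOQ): "
                    f"{o.upper} > {lql}")
        if infer_mode(self.has_censored, self.has_interval) != self.mode:
            raise ValidationError(
                f"mode {self.mode} inconsistent with data shape "
                f"(censored={self.has_censored}, interval={self.has_interval})")

    # derived quantities -------------------------------------------------------
    @property
    def n_detected(self) -> int:
        """Total weight of quantified (exact + interval) observations."""
        return sum(o.weight for o in self.observations if o.kind != "left_censored")

    @property
    def m_censored(self) -> int:
        """Total weight of below-LOQ (ND) observations."""
        return sum(o.weight for o in self.observations if o.kind == "left_censored")

    @property
    def total_weight(self) -> int:
        return sum(o.weight for o in self.observations)

    @property
    def has_censored(self) -> bool:
        return any(o.kind == "left_censored" for o in self.observations)

    @property
    def has_interval(self) -> bool:
        return any(o.kind == "interval" for o in self.observations)

    @property
    def loq_log10(self) -> float:
        return math.log10(self.loq)


# ---------------------------------------------------------------------------
# parsers


def _as_concentration(rec: object) -> float | None:
    """Interpret a raw record; None means an ND marker."""
    if isinstance(rec, str):
        tok = rec.strip()
        if tok.lower() in ND_TOKENS:
            return None
        try:
            return float(tok)
        except ValueError:
            raise ParseError(f"cannot interpret record {rec!r} as a concentration or ND")
    if isinstance(rec, (int, float)):
        return float(rec)
    raise ParseError(f"cannot interpret record {rec!r}")


def parse_quantitative(records: Iterable[object], loq: float,
                       label: str = "") -> EnumerationDataset:
    """Build a dataset from quantitative results (concentrations or ND flags).

    Detected concentrations become exact observations at their log10 value;
    ND records are pooled into one left-censored observation at the LOQ.
    ND means sub-LOQ presence (a value in (0, LOQ)), not a true zero.
    The mode is QN_3 if any ND is present, else QN_1.

    Raises
    ------
    ValidationError
        If a detected value lies below the LOQ (a data-entry contradiction)
        or every record is ND (no identifiable lognormal fit).
    ParseError
        For tokens that are neither numeric nor an ND marker.
    """
    if not (math.isfinite(loq) and loq > 0):
        raise ValidationError(f"loq must be positive and finite, got {loq!r}")
    obs: list[Observation] = []
    nd = 0
    for rec in records:
        conc = _as_concentration(rec)
        if conc is None:
            nd += 1
            continue
        if not conc > 0:
            raise ValidationError(f"detected concentration must be positive, got {conc}")
        if conc < loq * (1 - _BOUND_TOL):
            raise ValidationError(
                f"detected concentration {conc} CFU/g is below the LOQ {loq} CFU/g; "
                "values below the LOQ must be reported as ND")
        obs.append(Observation.exact(math.log10(conc)))
    if not obs:
        raise FullyCensoredError(
            "fully censored dataset: every record is ND; a lognormal fit is not "
            "identifiable from 100% left-censored (presence/absence) data")
    if nd:
        obs.append(Observation.left_censored(math.log10(loq), weight=nd))
    return EnumerationDataset(tuple(obs), loq, "QN_3" if nd else "QN_1", label)


def parse_interval_counts(bins: Iterable[Sequence[float]], nd_count: int,
                          loq: float, label: str = "") -> EnumerationDataset:
    """Build a dataset from semi-quantitative (binned) counts.

    ``bins`` holds ``(lower, upper, count)`` rows in linear CFU/g, e.g. the
    decade bands 10--10^2, 10^2--10^3, ...  Bins are half-open
    ``[lower, upper)``; the ND class is ``[0, LOQ)`` and enters as one
    left-censored observation of weight ``nd_count``.  Zero-count bins are
    dropped (blank cells in published tables are zero counts).
    """
    if not (math.isfinite(loq) and loq > 0):
        raise ValidationError(f"loq must be positive and finite, got {loq!r}")
    if not (isinstance(nd_count, int) and nd_count >= 0):
        raise ValidationError("nd_count must be a non-negative integer")
    cleaned: list[tuple[float, float, int]] = []
    for row in bins:
        lo, hi, count = float(row[0]), float(row[1]), row[2]
        count = int(count)
        if count < 0:
            raise ValidationError(f"bin count must be >= 0, got {count}")
        if not lo < hi:
            raise ValidationError(f"bin requires lower < upper, got [{lo}, {hi})")
        if lo < loq * (1 - _BOUND_TOL):
            raise ValidationError(
                f"bin lower bound {lo} CFU/g is below the LOQ {loq} CFU/g")
        cleaned.append((lo, hi, count))
    cleaned.sort(key=lambda b: b[0])
    for (lo1, hi1, _), (lo2, _, _) in zip(cleaned, cleaned[1:]):
        if lo2 < hi1 * (1 - _BOUND_TOL):
            raise ValidationError(
                f"overlapping bins: [{lo1}, {hi1}) and one starting at {lo2}")
    if sum(c for _, _, c in cleaned) == 0:
        raise ValidationError("all interval counts are zero; nothing to fit")
    obs = [Observation.interval(math.log10(lo), math.log10(hi), c)
           for lo, hi, c in cleaned if c > 0]
    if nd_count:
        obs.append(Observation.left_censored(math.log10(loq), weight=nd_count))
    return EnumerationDataset(tuple(obs), loq, "QN_4" if nd_count else "QN_2", label)


def censored_fraction(dataset: EnumerationDataset) -> Fraction:
    """Exact proportion of below-LOQ samples, as a rational number."""
    total = dataset.total_weight
    if total < 1:
        raise ValidationError("empty dataset")
    return Fraction(dataset.m_censored, total)


# ---------------------------------------------------------------------------
# fitting-convention transform


def to_fitting_convention(dataset: EnumerationDataset,
                          interval_method: str = "midpoint",
                          nd_bound: str = "integer") -> EnumerationDataset:
    """Re-express a dataset in the form the likelihood is evaluated on.

    ``interval_method``
        ``"midpoint"`` (default): each interval observation is replaced by
        an exact observation at the log10 of the arithmetic mid
        concentration of the band (10--10^2 CFU/g -> 55 CFU/g).  This is
        how semi-quantitative plate-count records are conventionally
        digitized for a point-data likelihood.
        ``"likelihood"``: intervals are kept and contribute their exact
        band probability (difference of normal CDFs).

    ``nd_bound``
        ``"integer"`` (default): the ND class is censored at LOQ - 1 CFU/g
        (for LOQ > 1), reading "below the LOQ" as "at most LOQ - 1 CFU/g"
        for integer colony-derived concentrations.
        ``"loq"``: censored exactly at the LOQ, the right choice for
        continuous-scale censoring (e.g. simulated data).
    """
    if interval_method not in ("midpoint", "likelihood"):
        raise ValidationError(f"unknown interval_method {interval_method!r}")
    if nd_bound not in ("integer", "loq"):
        raise ValidationError(f"unknown nd_bound {nd_bound!r}")
    new: list[Observation] = []
    for o in dataset.observations:
        if o.kind == "interval" and interval_method == "midpoint":
            mid = math.log10((10.0 ** o.lower + 10.0 ** o.upper) / 2.0)
            new.append(Observation.exact(mid, o.weight))
        elif o.kind == "left_censored" and nd_bound == "integer" and dataset.loq > 1:
            new.append(Observation.left_censored(math.log10(dataset.loq - 1), o.weight))
        else:
            new.append(o)
    has_c = any(o.kind == "left_censored" for o in new)
    has_i = any(o.kind == "interval" for o in new)
    return EnumerationDataset(tuple(new), dataset.loq,
                              infer_mode(has_c, has_i), dataset.label)


# ---------------------------------------------------------------------------
# serialization

_SCHEMA = 1


def dataset_to_json(dataset: EnumerationDataset) -> str:
    """Lossless JSON serialization (bit-exact round trip)."""
    doc = {
        "schema": _SCHEMA,
        "loq": dataset.loq,
        "mode": dataset.mode,
        "label": dataset.label,
        "observations": [
            {"kind": o.kind, "value": o.value, "lower": o.lower,
             "upper": o.upper, "weight": o.weight}
            for o in dataset.observations
        ],
    }
    return json.dumps(doc, indent=1)


def dataset_from_json(text: str) -> EnumerationDataset:
    doc = json.loads(text)
    obs = tuple(Observation(kind=o["kind"], value=o["value"], lower=o["lower"],
                            upper=o["upper"], weight=o["weight"])
                for o in doc["observations"])
    return EnumerationDataset(obs, doc["loq"], doc["mode"], doc.get("label", ""))


def _fmt(x: float) -> str:
    return repr(float(x))


def write_csv(dataset: EnumerationDataset, path: str | Path) -> None:
    """Write a dataset in the CSV interchange dialect matching its shape.

    Quantitative datasets (QN_1/QN_3) use dialect A: one column ``result``
    holding a concentration in CFU/g or the token ``ND`` (one row per
    sample).  Interval datasets (QN_2/QN_4) use dialect B: columns
    ``lower,upper,count`` in CFU/g with a distinguished ``ND,,<count>``
    row.  The LOQ and label are carried in ``#``-comment header lines.
    """
    lines = [f"# loq = {_fmt(dataset.loq)}"]
    if dataset.label:
        lines.append(f"# label = {dataset.label}")
    if dataset.has_interval:
        lines.append("lower,upper,count")
        for o in dataset.observations:
            if o.kind == "left_censored":
                lines.append(f"ND,,{o.weight}")
            elif o.kind == "interval":
                lines.append(f"{_fmt(10.0 ** o.lower)},{_fmt(10.0 ** o.upper)},{o.weight}")
            else:
                raise ValidationError(
                    "dialect B cannot carry exact observations; dataset mixes shapes")
    else:
        lines.append("result")
        for o in dataset.observations:
            token = "ND" if o.kind == "left_censored" else _fmt(10.0 ** o.value)
            lines.extend([token] * o.weight)
    Path(path).write_text("\n".join(lines) + "\n")


def _read_lines(path: str | Path) -> tuple[dict[str, str], list[str]]:
    meta: dict[str, str] = {}
    rows: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip().lower()] = val.strip()
            continue
        rows.append(line)
    return meta, rows


def read_csv(path: str | Path, loq: float | None = None,
             label: str | None = None) -> EnumerationDataset:
    """Read either CSV interchange dialect, auto-detected from the header.

    ``loq`` overrides (or supplies, when absent) the ``# loq = ...``
    comment line.
    """
    meta, rows = _read_lines(path)
    if loq is None:
        if "loq" not in meta:
            raise ParseError(f"{path}: no LOQ given and no '# loq = ...' header line")
        loq = float(meta["loq"])
    if label is None:
        label = meta.get("label", "")
    if not rows:
        raise ParseError(f"{path}: no data rows")
    header = [h.strip().lower() for h in rows[0].split(",")]
    if header == ["result"]:
        return parse_quantitative(rows[1:], loq, label)
    if header == ["lower", "upper", "count"]:
        bins = []
        nd = 0
        for line in rows[1:]:
            cells = [c.strip() for c in line.split(",")]
            if len(cells) != 3:
                raise ParseError(f"{path}: malformed row {line!r}")
            if cells[0].lower() in ND_TOKENS:
                nd += int(cells[2])
            else:
                bins.append((float(cells[0]), float(cells[1]), int(cells[2])))
        return parse_interval_counts(bins, nd, loq, label)
    raise ParseError(
        f"{path}: unrecognized header {rows[0]!r}; expected 'result' (dialect A) "
        "or 'lower,upper,count' (dialect B)")


def load_case(number: int) -> EnumerationDataset:
    """Load one of the four bundled semi-quantitative case-study tables.

    The bundled tables are published food-survey enumeration summaries
    (total coliforms and *B. cereus* in sandwiches, n = 1120; total
    coliforms and *E. coli* in retail beef, n = 100), all with LOQ =
    10 CFU/g and decade bins.
    """
    if number not in (1, 2, 3, 4):
        raise ValueError("case number must be 1..4")
    ref = resources.files("micromle.data") / f"case{number}.csv"
    with resources.as_file(ref) as p:
        return read_csv(p)
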