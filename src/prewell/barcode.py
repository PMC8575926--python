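"""Two-round combinatorial barcode model: whitelists, read layout, correction.

In pre-indexed microwell sequencing a cell is labeled twice. During in-cell
reverse transcription each sample well adds a well-specific RT barcode
(round 1) that encodes the sample or perturbation condition. After pooling
and loading into microwells, the bead that captures the cDNA contributes a
second barcode (round 2) that identifies the well/bead. A single cell's
reads therefore share the (round-1, round-2) pair — the :class:`CellKey` —
and demultiplexing reduces to recovering both barcodes from the barcode read.

The chemistry places the ligated bead oligo 5' of the RT-primer barcode,
which abuts the poly-T stretch, so the default barcode-read layout is

    round-2 bead barcode | UMI | round-1 RT barcode | poly-T tail

Segment lengths are not fixed by the chemistry; they are configuration with
the defaults below (18 / 8 / 10 nt).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np

from .errors import DataError, WhitelistError

DNA_ALPHABET = "ACGT"
_DNA_SET = frozenset(DNA_ALPHABET)

#: Segment names understood by :class:`ReadLayout`.
BARCODE_SEGMENTS = ("round2", "umi", "round1")


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings.

    Any character outside ACGT (e.g. ``N``) differs from every ACGT base,
    which the plain character comparison already guarantees because
    whitelists are ACGT-only.
    """
    if len(a) != len(b):
        raise ValueError(f"hamming: length mismatch ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class Whitelist:
    """A set of same-length ACGT barcodes.

    Round-1 whitelists enumerate the RT pre-index barcodes (one per sample
    well); round-2 whitelists enumerate the bead barcodes.
    """

    barcodes: frozenset
    length: int

    @classmethod
    def from_iterable(cls, barcodes: Iterable[str]) -> "Whitelist":
        seen: set = set()
        length = None
        for bc in barcodes:
            bc = bc.upper()
            if length is None:
                length = len(bc)
            elif len(bc) != length:
                raise WhitelistError(
                    f"mixed barcode lengths: expected {length}, got {len(bc)} for {bc!r}"
                )
            if not set(bc) <= _DNA_SET:
                raise WhitelistError(f"non-ACGT character in barcode {bc!r}")
            if bc in seen:
                raise WhitelistError(f"duplicate barcode {bc!r}")
            seen.add(bc)
        if not seen:
            raise WhitelistError("whitelist is empty")
        return cls(barcodes=frozenset(seen), length=length)

    def __contains__(self, bc: str) -> bool:
        return bc in self.barcodes

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.barcodes))

    def to_array(self) -> np.ndarray:
        """Barcodes as a (n, length) uint8 array of ASCII codes, sorted."""
        return np.frombuffer(
            "".join(sorted(self.barcodes)).encode("ascii"), dtype=np.uint8
        ).reshape(len(self), self.length)


def load_whitelist(path: str | os.PathLike) -> Whitelist:
    """Read a whitelist from a text file, one barcode per line.

    Blank lines and lines starting with ``#`` are ignored. Errors name the
    offending line.
    """
    entries: list = []
    seen: set = set()
    length = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            bc = line.upper()
            if not set(bc) <= _DNA_SET:
                raise WhitelistError(
                    f"{path}: line {lineno}: non-ACGT character in {bc!r}"
                )
            if length is None:
                length = len(bc)
            elif len(bc) != length:
                raise WhitelistError(
                    f"{path}: line {lineno}: barcode length {len(bc)} != {length}"
                )
            if bc in seen:
                raise WhitelistError(f"{path}: line {lineno}: duplicate barcode {bc}")
            seen.add(bc)
            entries.append(bc)
    if not entries:
        raise WhitelistError(f"{path}: whitelist is empty")
    return Whitelist(barcodes=frozenset(entries), length=length)


def write_whitelist(wl: Whitelist, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for bc in wl:
            fh.write(bc + "\n")


@dataclass(frozen=True)
class ReadLayout:
    """Positional schema of the barcode read.

    ``segment_order`` is a permutation of ``round2``/``umi``/``round1``,
    optionally followed by ``polyT``. The poly-T check, when enabled,
    requires at least ``polyT_min_frac`` of the first ``polyT_check_len``
    bases after the barcode segments to be T.
    """

    round2_len: int = 18
    umi_len: int = 8
    round1_len: int = 10
    segment_order: tuple = ("round2", "umi", "round1", "polyT")
    require_polyT: bool = False
    polyT_check_len: int = 10
    polyT_min_frac: float = 0.8

    def __post_init__(self):
        for name, val in (
            ("round2_len", self.round2_len),
            ("umi_len", self.umi_len),
            ("round1_len", self.round1_len),
            ("polyT_check_len", self.polyT_check_len),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        order = tuple(self.segment_order)
        object.__setattr__(self, "segment_order", order)
        core = [s for s in order if s != "polyT"]
        if sorted(core) != sorted(BARCODE_SEGMENTS):
            raise ValueError(
                f"segment_order must be a permutation of {BARCODE_SEGMENTS} "
                f"optionally followed by polyT, got {order}"
            )
        if "polyT" in order and order[-1] != "polyT":
            raise ValueError("polyT segment must come last")
        if not (0.0 < self.polyT_min_frac <= 1.0):
            raise ValueError("polyT_min_frac must be in (0, 1]")

    def segment_length(self, name: str) -> int:
        return {
            "round2": self.round2_len,
            "umi": self.umi_len,
            "round1": self.round1_len,
        }[name]

    @property
    def barcode_span(self) -> int:
        """Total length of the three barcode/UMI segments."""
        return self.round2_len + self.umi_len + self.round1_len

    @property
    def total_length(self) -> int:
        """Minimum read length needed to parse (incl. poly-T window if checked)."""
        n = self.barcode_span
        if self.require_polyT and "polyT" in self.segment_order:
            n += self.polyT_check_len
        return n

    def offsets(self) -> dict:
        """Start offset of each barcode segment in the read."""
        out = {}
        pos = 0
        for seg in self.segment_order:
            if seg == "polyT":
                out["polyT"] = pos
                break
            out[seg] = pos
            pos += self.segment_length(seg)
        return out


#: Named layout profiles shipped with the package.
LAYOUT_PROFILES = {"default": ReadLayout()}


def load_layout(source: str | os.PathLike | None = None, **overrides) -> ReadLayout:
    """Resolve a layout from a profile name, a ``key=value`` config file, or kwargs."""
    import dataclasses

    if source is None:
        base = {}
    elif isinstance(source, str) and source in LAYOUT_PROFILES and not os.path.exists(source):
        base = dataclasses.asdict(LAYOUT_PROFILES[source])
    else:
        base = _parse_layout_file(source)
    base.update(overrides)
    return ReadLayout(**base)


def _parse_layout_file(path) -> dict:
    fields = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise DataError(f"{path}: line {lineno}: expected key=value")
            key, val = (s.strip() for s in line.split("=", 1))
            if key in ("round2_len", "umi_len", "round1_len", "polyT_check_len"):
                fields[key] = int(val)
            elif key == "polyT_min_frac":
                fields[key] = float(val)
            elif key == "require_polyT":
                fields[key] = val.lower() in ("1", "true", "yes", "on")
            elif key == "segment_order":
                fields[key] = tuple(s.strip() for s in val.split(","))
            else:
                raise DataError(f"{path}: line {lineno}: unknown layout key {key!r}")
    return fields


class CellKey(NamedTuple):
    """The (round-1, round-2) barcode pair that names one cell identity."""

    round1: str
    round2: str

    def __str__(self) -> str:
        return f"{self.round1}-{self.round2}"

    @classmethod
    def from_string(cls, s: str) -> "CellKey":
        r1, sep, r2 = s.partition("-")
        if not sep or not r1 or not r2:
            raise DataError(f"malformed cell id {s!r}, expected 'round1-round2'")
        return cls(r1, r2)


@dataclass
class ParsedBarcodeRead:
    """Segments sliced from one barcode read, plus QC flags.

    Flags: ``too_short`` (read shorter than the layout; segments absent) and
    ``polyT_fail`` (poly-T check enabled and not met).
    """

    round1_obs: str | None
    round2_obs: str | None
    umi: str | None
    qc_flags: frozenset = frozenset()

    @property
    def ok(self) -> bool:
        return not self.qc_flags


def parse_barcode_read(seq: str, layout: ReadLayout) -> ParsedBarcodeRead:
    """Slice barcode/UMI segments from a read at the layout's fixed offsets."""
    seq = seq.upper()
    if len(seq) < layout.total_length:
        return ParsedBarcodeRead(None, None, None, frozenset({"too_short"}))
    offs = layout.offsets()
    segs = {
        name: seq[offs[name] : offs[name] + layout.segment_length(name)]
        for name in BARCODE_SEGMENTS
    }
    flags = set()
    if layout.require_polyT and "polyT" in offs:
        window = seq[offs["polyT"] : offs["polyT"] + layout.polyT_check_len]
        if window.count("T") < int(np.ceil(layout.polyT_min_frac * layout.polyT_check_len)):
            flags.add("polyT_fail")
    return ParsedBarcodeRead(
        round1_obs=segs["round1"],
        round2_obs=segs["round2"],
        umi=segs["umi"],
        qc_flags=frozenset(flags),
    )


@dataclass(frozen=True)
class CorrectionResult:
    """Outcome of whitelist-based barcode correction.

    ``status`` is ``exact`` (in the whitelist), ``corrected`` (exactly one
    whitelist entry within the allowed Hamming distance), ``ambiguous``
    (two or more), or ``unmatched`` (none).
    """

    status: str
    barcode: str | None = None
    distance: int = 0

    def __post_init__(self):
        if self.status not in ("exact", "corrected", "ambiguous", "unmatched"):
            raise ValueError(f"invalid status {self.status!r}")
        if self.status == "exact" and self.distance != 0:
            raise ValueError("exact match must have distance 0")
        if self.status in ("ambiguous", "unmatched") and self.barcode is not None:
            raise ValueError(f"{self.status} result must not carry a barcode")

    @property
    def resolved(self) -> bool:
        return self.status in ("exact", "corrected")


def correct_barcode(observed: str, wl: Whitelist, max_dist: int = 1) -> CorrectionResult:
    """Correct one observed barcode against a whitelist by Hamming scan.

    Substitution-only: the fixed-position layout makes substitutions the
    dominant recoverable error, so indels are out of scope. ``N`` (or any
    non-ACGT character) mismatches every base.
    """
    if max_dist not in (0, 1, 2):
        raise ValueError(f"max_dist must be 0, 1 or 2, got {max_dist}")
    observed = observed.upper()
    if len(observed) != wl.length:
        raise DataError(
            f"observed barcode length {len(observed)} != whitelist length {wl.length}"
        )
    if observed in wl:
        return CorrectionResult("exact", observed, 0)
    hits = []
    for bc in wl:
        d = hamming(observed, bc)
        if d <= max_dist:
            hits.append((d, bc))
    if not hits:
        return CorrectionResult("unmatched")
    if len(hits) > 1:
        return CorrectionResult("ambiguous")
    d, bc = hits[0]
    return CorrectionResult("corrected", bc, d)


class BarcodeCorrector:
    """Whitelist corrector with precomputed 1-mutant neighborhood.

    Semantics are identical to :func:`correct_barcode`; this class exists so
    the per-read demultiplexing loop pays a dict lookup instead of a scan.
    For ``max_dist=2`` it falls back to a vectorized scan.
    """

    _AMBIG = object()

    def __init__(self, wl: Whitelist, max_dist: int = 1):
        if max_dist not in (0, 1, 2):
            raise ValueError(f"max_dist must be 0, 1 or 2, got {max_dist}")
        self.wl = wl
        self.max_dist = max_dist
        self._exact = wl.barcodes
        self._neighbors: dict = {}
        if max_dist >= 1:
            for bc in wl:
                for i in range(wl.length):
                    for base in DNA_ALPHABET:
                        if base == bc[i]:
                            continue
                        mut = bc[:i] + base + bc[i + 1 :]
                        if mut in self._neighbors and self._neighbors[mut] != bc:
                            self._neighbors[mut] = self._AMBIG
                        else:
                            self._neighbors[mut] = bc
        self._arr = wl.to_array()
        self._sorted = sorted(wl.barcodes)

    def correct(self, observed: str) -> CorrectionResult:
        observed = observed.upper()
        if len(observed) != self.wl.length:
            raise DataError(
                f"observed barcode length {len(observed)} != whitelist length "
                f"{self.wl.length}"
            )
        if observed in self._exact:
            return CorrectionResult("exact", observed, 0)
        if self.max_dist == 0:
            return CorrectionResult("unmatched")
        if self.max_dist == 1 and set(observed) <= _DNA_SET:
            hit = self._neighbors.get(observed)
            if hit is None:
                return CorrectionResult("unmatched")
            if hit is self._AMBIG:
                return CorrectionResult("ambiguous")
            return CorrectionResult("corrected", hit, 1)
        # max_dist == 2, or non-ACGT characters (N counts as a mismatch
        # everywhere, so the 1-mutant map does not apply): full scan
        obs = np.frombuffer(observed.encode("ascii"), dtype=np.uint8)
        dists = (self._arr != obs).sum(axis=1)
        within = np.flatnonzero(dists <= self.max_dist)
        if within.size == 0:
            return CorrectionResult("unmatched")
        if within.size > 1:
            return CorrectionResult("ambiguous")
        i = int(within[0])
        return CorrectionResult("corrected", self._sorted[i], int(dists[i]))


def random_whitelist(
    n: int,
    length: int,
    rng: np.random.Generator,
    min_pairwise_dist: int = 3,
) -> Whitelist:
    """Draw ``n`` random barcodes with pairwise Hamming distance >= ``min_pairwise_dist``.

    Distance 3 guarantees single-substitution correction is never ambiguous.
    Rejection sampling; raises if the code cannot be filled in a reasonable
    number of attempts (length too short for n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < 1:
        raise ValueError("length must be >= 1")
    accepted = np.empty((n, length), dtype=np.uint8)
    alphabet = np.frombuffer(DNA_ALPHABET.encode("ascii"), dtype=np.uint8)
    count = 0
    attempts = 0
    max_attempts = 200 * n + 1000
    while count < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not draw {n} barcodes of length {length} with pairwise "
                f"distance >= {min_pairwise_dist}"
            )
        cand = alphabet[rng.integers(0, 4, size=length)]
        if count and min_pairwise_dist > 1:
            if ((accepted[:count] != cand).sum(axis=1) < min_pairwise_dist).any():
                continue
        elif count:
            if (accepted[:count] == cand).all(axis=1).any():
                continue
        accepted[count] = cand
        count += 1
    codes = [bytes(row).decode("ascii") for row in accepted]
    return Whitelist.from_iterable(codes)
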