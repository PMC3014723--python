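"""Delimited-text formats: tally sheets, ground-truth sheets, taxa files.

All tabular files are comma-separated UTF-8 with a header row, preceded by a
``#`` provenance comment embedding the package version, a hash of the run
configuration, and the seed. Readers skip ``#`` lines.

Tally-sheet format (what a technician records, one row per observation):

    sample_id, phase, cell_index, taxon_id, count

* phase 1 (sieve): ``cell_index`` blank; per-taxon large-specimen counts.
* phase 2 (subsample): ``cell_index`` in [1, n_complete_cells]; per-cell,
  per-taxon counts. Cells appear in the order they were counted; a counted
  cell in which nothing was seen is recorded as a single row with blank
  ``taxon_id`` and count 0, so the number and order of counted cells survive
  a round trip.
* phase 3 (quick scan): ``cell_index`` and ``count`` blank; one presence row
  per newly seen taxon.

Ground-truth sheets (simulation output) use

    sample_id, region, taxon_id, count

with region ``large``, ``edge`` or ``cell:<i>``.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .community import SampleRealization, TaxonSpec
from .geometry import TrayGeometry
from .protocol import ProtocolResult, SubsampleResult

__all__ = [
    "TallyFormatError",
    "TallySample",
    "provenance_line",
    "write_tally_sheet",
    "read_tally_sheet",
    "write_truth_sheet",
    "read_truth_sheet",
    "read_taxa_file",
    "write_taxa_file",
    "tally_from_protocol",
    "protocol_from_tally",
]

TALLY_HEADER = ["sample_id", "phase", "cell_index", "taxon_id", "count"]
TRUTH_HEADER = ["sample_id", "region", "taxon_id", "count"]
TAXA_HEADER = ["taxon_id", "relative_abundance", "large_fraction",
               "p_detect_cell", "p_detect_scan_per_individual"]


class TallyFormatError(ValueError):
    """Malformed tally/truth file; message carries the offending line number."""


def provenance_line(config: dict | None = None, seed=None) -> str:
    """Comment line embedding version, config hash and seed."""
    digest = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return f"# subtray v{__version__} config_hash={digest} seed={seed}"


@dataclass
class TallySample:
    """One sample's records as read from (or written to) a tally sheet."""

    sample_id: str
    large_counts: dict[str, int] = field(default_factory=dict)
    #: ordered (cell_index, {taxon: count}) in counting order
    cells: list[tuple[int, dict[str, int]]] = field(default_factory=list)
    scan_taxa: set[str] = field(default_factory=set)

    @property
    def k(self) -> int:
        return len(self.cells)

    @property
    def taxon_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.large_counts:
            seen.setdefault(t)
        for _, counts in self.cells:
            for t in counts:
                seen.setdefault(t)
        for t in sorted(self.scan_taxa):
            seen.setdefault(t)
        return tuple(seen)


def tally_from_protocol(sample_id: str, result: ProtocolResult) -> TallySample:
    """Flatten a protocol result into tally records (1-based cell indices)."""
    ts = TallySample(sample_id=sample_id)
    for taxon, n in zip(result.taxon_ids, result.large_counts):
        if n > 0:
            ts.large_counts[taxon] = int(n)
    for cell, row in zip(result.subsample.selected_cells,
                         result.subsample.observed_counts):
        counts = {t: int(c) for t, c in zip(result.taxon_ids, row) if c > 0}
        ts.cells.append((int(cell) + 1, counts))
    ts.scan_taxa = set(result.scan_taxa)
    return ts


def protocol_from_tally(ts: TallySample) -> ProtocolResult:
    """Rebuild a ProtocolResult from tally records (real-data mode).

    Detection is not re-modelled: the records are taken as what was observed.
    """
    taxa = ts.taxon_ids
    index = {t: i for i, t in enumerate(taxa)}
    large = np.zeros(len(taxa), dtype=int)
    for t, n in ts.large_counts.items():
        large[index[t]] = n
    observed = np.zeros((ts.k, len(taxa)), dtype=int)
    cells = np.array([c for c, _ in ts.cells], dtype=int) - 1
    for i, (_, counts) in enumerate(ts.cells):
        for t, n in counts.items():
            observed[i, index[t]] = n
    sub = SubsampleResult(selected_cells=cells, observed_counts=observed,
                          k=ts.k)
    return ProtocolResult(taxon_ids=taxa, large_counts=large, subsample=sub,
                          scan_taxa=frozenset(ts.scan_taxa), k_used=ts.k)


def write_tally_sheet(path, samples: list[TallySample],
                      config: dict | None = None, seed=None) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write(provenance_line(config, seed) + "\n")
        writer = csv.writer(fh)
        writer.writerow(TALLY_HEADER)
        for ts in samples:
            for taxon, n in ts.large_counts.items():
                writer.writerow([ts.sample_id, 1, "", taxon, n])
            for cell, counts in ts.cells:
                if not counts:
                    writer.writerow([ts.sample_id, 2, cell, "", 0])
                for taxon, n in counts.items():
                    writer.writerow([ts.sample_id, 2, cell, taxon, n])
            for taxon in sorted(ts.scan_taxa):
                writer.writerow([ts.sample_id, 3, "", taxon, ""])


def _rows(path):
    """Yield (lineno, row) for data rows, skipping comments and blanks."""
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (row[0].startswith("#")):
                continue
            yield lineno, row


def read_tally_sheet(path, n_complete_cells: int = 45) -> list[TallySample]:
    """Parse and validate a tally sheet into per-sample records.

    Raises :class:`TallyFormatError` (with the line number) on malformed
    rows, duplicate phase-2 (cell, taxon) entries, or cell indices outside
    [1, ``n_complete_cells``].
    """
    samples: dict[str, TallySample] = {}
    seen_pairs: set[tuple[str, int, str]] = set()
    header_seen = False
    for lineno, row in _rows(path):
        if not header_seen:
            if [c.strip() for c in row] != TALLY_HEADER:
                raise TallyFormatError(
                    f"line {lineno}: expected header {TALLY_HEADER}")
            header_seen = True
            continue
        if len(row) != 5:
            raise TallyFormatError(f"line {lineno}: expected 5 fields")
        sid, phase_s, cell_s, taxon, count_s = (c.strip() for c in row)
        if phase_s not in {"1", "2", "3"}:
            raise TallyFormatError(f"line {lineno}: phase must be 1, 2 or 3")
        phase = int(phase_s)
        ts = samples.setdefault(sid, TallySample(sample_id=sid))
        if phase == 2:
            try:
                cell = int(cell_s)
            except ValueError:
                raise TallyFormatError(
                    f"line {lineno}: phase-2 row needs a cell_index") from None
            if not 1 <= cell <= n_complete_cells:
                raise TallyFormatError(
                    f"line {lineno}: cell_index {cell} outside "
                    f"[1, {n_complete_cells}]")
            key = (sid, cell, taxon)
            if taxon and key in seen_pairs:
                raise TallyFormatError(
                    f"line {lineno}: duplicate (sample, cell, taxon) row")
            seen_pairs.add(key)
            count = _parse_count(count_s, lineno)
            entry = next((counts for c, counts in ts.cells if c == cell), None)
            if entry is None:
                entry = {}
                ts.cells.append((cell, entry))
            if taxon:
                entry[taxon] = count
            elif count != 0:
                raise TallyFormatError(
                    f"line {lineno}: blank taxon allowed only as an "
                    "empty-cell marker with count 0")
        elif phase == 1:
            if cell_s:
                raise TallyFormatError(
                    f"line {lineno}: phase-1 row must leave cell_index blank")
            if not taxon:
                raise TallyFormatError(f"line {lineno}: phase-1 row needs a taxon")
            if taxon in ts.large_counts:
                raise TallyFormatError(
                    f"line {lineno}: duplicate phase-1 taxon {taxon!r}")
            ts.large_counts[taxon] = _parse_count(count_s, lineno)
        else:  # phase 3: presence only
            if cell_s or count_s:
                raise TallyFormatError(
                    f"line {lineno}: phase-3 rows carry taxon presence only")
            if not taxon:
                raise TallyFormatError(f"line {lineno}: phase-3 row needs a taxon")
            ts.scan_taxa.add(taxon)
    if not header_seen:
        raise TallyFormatError("empty file: missing header row")
    for ts in samples.values():
        phase12 = set(ts.large_counts) | {
            t for _, counts in ts.cells for t, n in counts.items() if n > 0}
        overlap = ts.scan_taxa & phase12
        if overlap:
            raise TallyFormatError(
                f"sample {ts.sample_id!r}: scan taxa {sorted(overlap)} "
                "already recorded in phases 1-2")
    return list(samples.values())


def _parse_count(text: str, lineno: int) -> int:
    try:
        n = int(text)
    except ValueError:
        raise TallyFormatError(
            f"line {lineno}: count {text!r} is not an integer") from None
    if n < 0:
        raise TallyFormatError(f"line {lineno}: negative count")
    return n


# -- ground-truth sheets ----------------------------------------------------

def write_truth_sheet(path, samples: list[tuple[str, SampleRealization]],
                      config: dict | None = None, seed=None) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write(provenance_line(config, seed) + "\n")
        writer = csv.writer(fh)
        writer.writerow(TRUTH_HEADER)
        for sid, sample in samples:
            ids = sample.taxon_ids
            for taxon, n in zip(ids, sample.large_counts):
                if n > 0:
                    writer.writerow([sid, "large", taxon, int(n)])
            C = sample.geometry.n_complete_cells
            for region_i in range(C + 1):
                region = "edge" if region_i == C else f"cell:{region_i + 1}"
                for taxon, n in zip(ids, sample.cell_counts[region_i]):
                    if n > 0:
                        writer.writerow([sid, region, taxon, int(n)])


def read_truth_sheet(path, taxa: tuple[TaxonSpec, ...],
                     geometry: TrayGeometry | None = None
                     ) -> list[tuple[str, SampleRealization]]:
    """Rebuild ground-truth samples; ``taxa`` supplies detection parameters."""
    if geometry is None:
        geometry = TrayGeometry()
    index = {t.taxon_id: i for i, t in enumerate(taxa)}
    C = geometry.n_complete_cells
    data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    header_seen = False
    for lineno, row in _rows(path):
        if not header_seen:
            if [c.strip() for c in row] != TRUTH_HEADER:
                raise TallyFormatError(
                    f"line {lineno}: expected header {TRUTH_HEADER}")
            header_seen = True
            continue
        if len(row) != 4:
            raise TallyFormatError(f"line {lineno}: expected 4 fields")
        sid, region, taxon, count_s = (c.strip() for c in row)
        if taxon not in index:
            raise TallyFormatError(
                f"line {lineno}: unknown taxon {taxon!r} for this community")
        cells, large = data.setdefault(
            sid, (np.zeros((C + 1, len(taxa)), dtype=int),
                  np.zeros(len(taxa), dtype=int)))
        n = _parse_count(count_s, lineno)
        if region == "large":
            large[index[taxon]] += n
        elif region == "edge":
            cells[C, index[taxon]] += n
        elif region.startswith("cell:"):
            cell = int(region.split(":", 1)[1])
            if not 1 <= cell <= C:
                raise TallyFormatError(f"line {lineno}: cell {cell} out of range")
            cells[cell - 1, index[taxon]] += n
        else:
            raise TallyFormatError(f"line {lineno}: unknown region {region!r}")
    if not header_seen:
        raise TallyFormatError("empty file: missing header row")
    return [(sid, SampleRealization(taxa=taxa, geometry=geometry,
                                    cell_counts=cells, large_counts=large))
            for sid, (cells, large) in data.items()]


# -- taxa preset files ------------------------------------------------------

def write_taxa_file(path, taxa: tuple[TaxonSpec, ...]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TAXA_HEADER)
        for t in taxa:
            writer.writerow([t.taxon_id, repr(t.relative_abundance),
                             t.large_fraction, t.p_detect_cell,
                             t.p_detect_scan_per_individual])


def read_taxa_file(path) -> tuple[TaxonSpec, ...]:
    taxa = []
    header_seen = False
    for lineno, row in _rows(path):
        if not header_seen:
            if [c.strip() for c in row] != TAXA_HEADER:
                raise TallyFormatError(
                    f"line {lineno}: expected header {TAXA_HEADER}")
            header_seen = True
            continue
        if len(row) != 5:
            raise TallyFormatError(f"line {lineno}: expected 5 fields")
        try:
            taxa.append(TaxonSpec(taxon_id=row[0].strip(),
                                  relative_abundance=float(row[1]),
                                  large_fraction=float(row[2]),
                                  p_detect_cell=float(row[3]),
                                  p_detect_scan_per_individual=float(row[4])))
        except ValueError as exc:
            raise TallyFormatError(f"line {lineno}: {exc}") from None
    if not header_seen:
        raise TallyFormatError("empty file: missing header row")
    return tuple(taxa)
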