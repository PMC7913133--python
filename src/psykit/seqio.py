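"""Sequence and tabular I/O for PSY precursor screening.

Holds the precursor record container, FASTA reading/writing (via Biopython),
NCBI BLAST tabular ingest, and the UniProt accession manifest for the 32
published PSY homologs, with an optional cached fetch.

Coordinates are 0-based half-open internally; rendered reports are 1-based
inclusive.
"""

from __future__ import annotations

import hashlib
import json
import re
import urllib.error
import urllib.request
import warnings
from dataclasses import dataclass, field
from datetime import date
from io import StringIO
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Residue alphabet accepted in a PrecursorRecord: standard residues plus X.
SEQUENCE_ALPHABET = STANDARD_AA | {"X"}

UNIPROT_ACCESSION_RE = re.compile(
    r"^([OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9]([A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)


class SeqParseError(ValueError):
    """Raised when a sequence or table file cannot be parsed."""


@dataclass(frozen=True)
class PrecursorRecord:
    """One candidate or known prepropeptide sequence.

    Parameters
    ----------
    id : str
        Short unique identifier, e.g. ``"AtPSY2"``.
    sequence : str
        Uppercase amino-acid string over the 20 standard residues plus X.
    accession : str, optional
        UniProt accession.
    species : str, optional
        Source species.
    annotations : dict
        Free-form string annotations, e.g. a precomputed signal-peptide
        span as ``{"signal_peptide": "1-25"}`` (1-based inclusive).
    """

    id: str
    sequence: str
    accession: str | None = None
    species: str | None = None
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal residues {sorted(bad)}; "
                "allowed are the 20 standard amino acids plus X"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_sequence(raw: str, *, record_id: str = "?") -> str:
    """Uppercase a raw sequence and map it onto the package alphabet.

    ``*`` stop characters are stripped and selenocysteine ``U`` is mapped to
    ``X``, each with a warning; any other non-standard letter raises.
    """
    seq = raw.upper().replace(" ", "")
    if "*" in seq:
        warnings.warn(f"record {record_id!r}: stripping '*' stop character(s)")
        seq = seq.replace("*", "")
    if "U" in seq:
        warnings.warn(f"record {record_id!r}: mapping selenocysteine U -> X")
        seq = seq.replace("U", "X")
    bad = set(seq) - SEQUENCE_ALPHABET
    if bad:
        raise SeqParseError(
            f"record {record_id!r}: illegal residues {sorted(bad)}"
        )
    return seq


def _validate_fasta_layout(text: str, origin: str) -> None:
    """Light structural pass so errors can name a line number."""
    saw_header = False
    header_line = 0
    body_count = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if saw_header and body_count == 0:
                raise SeqParseError(
                    f"{origin}: empty sequence for header at line {header_line}"
                )
            if stripped == ">":
                raise SeqParseError(f"{origin}: empty FASTA header at line {lineno}")
            saw_header = True
            header_line = lineno
            body_count = 0
        else:
            if not saw_header:
                raise SeqParseError(
                    f"{origin}: sequence data before any '>' header at line {lineno}"
                )
            body_count += 1
    if saw_header and body_count == 0:
        raise SeqParseError(f"{origin}: empty sequence for header at line {header_line}")


def read_fasta(path: str | Path) -> list[PrecursorRecord]:
    """Read a (wrapped or unwrapped) multi-record FASTA file.

    Order is preserved; sequences are uppercased and normalized
    (see :func:`normalize_sequence`).
    """
    path = Path(path)
    text = path.read_text()
    _validate_fasta_layout(text, str(path))
    records = []
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        records.append(
            PrecursorRecord(
                id=rec.id,
                sequence=normalize_sequence(str(rec.seq), record_id=rec.id),
            )
        )
    return records


def write_fasta(records: list[PrecursorRecord], path: str | Path, *, wrap: int = 60) -> None:
    """Write records to FASTA, wrapping sequence lines at ``wrap`` columns."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i : i + wrap] + "\n")


@dataclass(frozen=True)
class BlastHit:
    """One row of a BLAST hit table (BLAST execution is external)."""

    query_id: str
    subject_id: str
    evalue: float
    subject_length: int | None = None
    percent_identity: float | None = None
    bitscore: float | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"hit {self.subject_id!r}: evalue must be >= 0")
        if self.subject_length is not None and self.subject_length < 1:
            raise ValueError(f"hit {self.subject_id!r}: subject_length must be >= 1")


def read_blast_tab(path: str | Path) -> list[BlastHit]:
    """Read BLAST tabular output into :class:`BlastHit` rows.

    Two dialects are accepted, detected per file from the column count:

    * the standard 12-column NCBI tabular format (``-outfmt 6``): qseqid,
      sseqid, pident, length, mismatch, gapopen, qstart, qend, sstart, send,
      evalue, bitscore.  This dialect carries no subject length, so
      ``subject_length`` is left unset.
    * a minimal 3-column dialect: subject_id, subject_length, evalue
      (query_id is recorded as ``"-"``).
    """
    path = Path(path)
    hits: list[BlastHit] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        try:
            if len(cols) >= 12:
                hits.append(
                    BlastHit(
                        query_id=cols[0],
                        subject_id=cols[1],
                        percent_identity=float(cols[2]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                    )
                )
            elif len(cols) == 3:
                hits.append(
                    BlastHit(
                        query_id="-",
                        subject_id=cols[0],
                        subject_length=int(cols[1]),
                        evalue=float(cols[2]),
                    )
                )
            else:
                raise SeqParseError(
                    f"{path}:{lineno}: expected 12+ or 3 tab-separated columns, got {len(cols)}"
                )
        except ValueError as exc:
            raise SeqParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


# Published manifest of the 32 PSY homologs used in the cross-species
# alignment: (name, UniProt accession), ordered as published.
DEFAULT_MANIFEST_ENTRIES: tuple[tuple[str, str], ...] = (
    ("AtPSY1", "Q941C7"),
    ("AtPSY2", "Q8LE92"),
    ("AtPSY3", "Q8S8P7"),
    ("AtPSY4", "B3H674"),
    ("AtPSY5", "Q1G3G7"),
    ("AtPSY6", "A0MDK8"),
    ("AtPSY7", "Q3E7N2"),
    ("AtPSY8", "Q9SN87"),
    ("AmtPSY", "W1PCD7"),
    ("OsPSY1", "A2ZX08"),
    ("OsPSY2", "Q5TKN9"),
    ("OsPSY3", "Q5NBP8"),
    ("OsPSY4", "Q9LDG6"),
    ("OsPSY5", "Q5N756"),
    ("OsPSY6", "Q75KZ0"),
    ("OsPSY7", "B9FKV0"),
    ("ZmPSY1", "B6TP25"),
    ("ZmPSY2", "B6U638"),
    ("ZmPSY3", "B6SX29"),
    ("ZmPSY4", "B6UG95"),
    ("ZmPSY5", "B6TWC1"),
    ("ZmPSY6", "B6SJ20"),
    ("ZmPSY7", "B6SK20"),
    ("ZmPSY8", "B6T2H1"),
    ("GmPSY1", "C6T043"),
    ("GmPSY2", "C6SWX4"),
    ("GmPSY3", "C6T324"),
    ("CaPSY1", "Q8GTD8"),
    ("LjPSY1", "I3SPZ1"),
    ("PtPSY1", "A9P872"),
    ("MtPSY1", "A2Q4B1"),
    ("PpPSY", "A0A2K1K614"),
)


@dataclass(frozen=True)
class AccessionManifest:
    """Ordered (name, UniProt accession) manifest; defaults to the 32 homologs."""

    entries: tuple[tuple[str, str], ...] = DEFAULT_MANIFEST_ENTRIES

    def __post_init__(self) -> None:
        for name, acc in self.entries:
            if not UNIPROT_ACCESSION_RE.match(acc):
                raise ValueError(f"{name}: {acc!r} is not a valid UniProt accession")
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate names in manifest")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AccessionManifest":
        entries = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            name, acc = line.split("\t")[:2]
            entries.append((name.strip(), acc.strip()))
        return cls(entries=tuple(entries))

    def __len__(self) -> int:
        return len(self.entries)


UNIPROT_FASTA_URL = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"


def cache_fasta_path(cache_dir: str | Path) -> Path:
    return Path(cache_dir) / "manifest_sequences.fasta"


def load_cached_accessions(
    manifest: AccessionManifest, cache_dir: str | Path
) -> list[PrecursorRecord] | None:
    """Load previously fetched manifest sequences, or None if incomplete."""
    fasta = cache_fasta_path(cache_dir)
    if not fasta.exists():
        return None
    by_id = {rec.id: rec for rec in read_fasta(fasta)}
    out = []
    for name, acc in manifest.entries:
        rec = by_id.get(name)
        if rec is None:
            return None
        out.append(
            PrecursorRecord(id=name, sequence=rec.sequence, accession=acc)
        )
    return out


def fetch_accessions(
    manifest: AccessionManifest,
    cache_dir: str | Path,
    *,
    timeout: float = 30.0,
) -> list[PrecursorRecord]:
    """Fetch manifest sequences from UniProtKB, caching them as FASTA.

    Purely optional for every other module: all screening, alignment and
    census code accepts records from any source.  On a cache hit no network
    access happens.  Failures are collected per entry and raised together,
    never silently dropped.  The cache metadata records the fetch date and a
    SHA-256 checksum per sequence, since UniProt entries are versioned.
    """
    cache_dir = Path(cache_dir)
    cached = load_cached_accessions(manifest, cache_dir)
    if cached is not None:
        return cached
    cache_dir.mkdir(parents=True, exist_ok=True)
    records: list[PrecursorRecord] = []
    failures: list[tuple[str, str, str]] = []
    for name, acc in manifest.entries:
        url = UNIPROT_FASTA_URL.format(acc=acc)
        try:
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                text = resp.read().decode()
            seqs = list(SeqIO.parse(StringIO(text), "fasta"))
            if not seqs:
                raise SeqParseError("empty FASTA response")
            seq = normalize_sequence(str(seqs[0].seq), record_id=name)
            records.append(PrecursorRecord(id=name, sequence=seq, accession=acc))
        except (urllib.error.URLError, OSError, SeqParseError, ValueError) as exc:
            failures.append((name, acc, str(exc)))
    if failures:
        report = "; ".join(f"{n} ({a}): {m}" for n, a, m in failures)
        raise RuntimeError(f"failed to fetch {len(failures)} accession(s): {report}")
    write_fasta(records, cache_fasta_path(cache_dir))
    meta = {
        "fetch_date": date.today().isoformat(),
        "sha256": {
            rec.id: hashlib.sha256(rec.sequence.encode()).hexdigest()
            for rec in records
        },
    }
    (cache_dir / "manifest_meta.json").write_text(json.dumps(meta, indent=2))
    return records


def records_to_seqrecords(records: list[PrecursorRecord]) -> list[SeqRecord]:
    """Convert to Biopython SeqRecords (for interop with Bio.* tooling)."""
    return [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
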