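"""Reading, QC-screening and subsetting of codon-aligned mtCOI data.

The quality screen mirrors the standard guard against NUMTs (nuclear
copies of mitochondrial genes) in single-marker population genetics:
a genuine protein-coding mtCOI read must keep an open reading frame, so
sequences with frame-shifting indels or internal stop codons under the
invertebrate mitochondrial code are rejected.

Columns are 0-based everywhere inside the package; user-facing reports
print 1-based positions.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from . import codons

IUPAC_DNA = set("ACGTRYSWKMBDHVN-")
ACGT = set("ACGT")

SAMPLE_SHEET_COLUMNS = ("id", "species", "region", "site")


@dataclass
class SequenceRecord:
    """One aligned mtCOI sequence with its specimen metadata."""

    id: str
    seq: str
    species: str = ""
    region: str = ""
    site: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record has an empty id")
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.seq):
            if ch not in IUPAC_DNA:
                raise ValueError(
                    f"record {self.id!r}: non-IUPAC character {ch!r} "
                    f"at position {pos + 1}"
                )

    @property
    def ungapped(self) -> str:
        return self.seq.replace("-", "")


@dataclass
class CodonAlignment:
    """Equal-length aligned coding sequences plus reading-frame context."""

    records: list[SequenceRecord]
    frame_offset: int = 0
    genetic_code: int = codons.INVERTEBRATE_MITO_ID

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment contains no sequences")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"unequal aligned lengths: {sorted(lengths)}")
        seen: set[str] = set()
        for r in self.records:
            if r.id in seen:
                raise ValueError(f"duplicate sequence id: {r.id!r}")
            seen.add(r.id)

    @property
    def length(self) -> int:
        """Aligned length (the Sites_alignment of a diversity table)."""
        return len(self.records[0].seq)

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def get(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(f"unknown sequence id: {rec_id!r}")

    def subset(self, ids: Sequence[str]) -> "CodonAlignment":
        return CodonAlignment([self.get(i) for i in ids],
                              self.frame_offset, self.genetic_code)


@dataclass
class SiteMask:
    """Strictly increasing 0-based column indices retained for analysis."""

    used: list[int]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.used, self.used[1:])):
            raise ValueError("mask indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.used)

    def apply(self, seq: str) -> str:
        return "".join(seq[i] for i in self.used)

    def codon_triples(self, frame_offset: int) -> list[tuple[int, int, int]]:
        """In-frame codon column triples fully contained in the mask.

        Only whole codons whose three alignment columns are all retained
        contribute to synonymous/nonsynonymous analyses.
        """
        kept = set(self.used)
        triples = []
        if not self.used:
            return triples
        last = max(self.used)
        for start in range(frame_offset, last - 1, 3):
            t = (start, start + 1, start + 2)
            if all(c in kept for c in t):
                triples.append(t)
        return triples


@dataclass
class PopulationSample:
    """A per-site subset of an alignment restricted to complete columns."""

    alignment: CodonAlignment
    mask: SiteMask
    species: str = ""
    region: str = ""
    site: str = ""
    excluded: bool = False  # below the n>=4 estimation gate

    @property
    def n(self) -> int:
        return len(self.alignment)

    @property
    def sites_used(self) -> int:
        return len(self.mask)

    @property
    def sites_alignment(self) -> int:
        return self.alignment.length

    def masked_seqs(self) -> list[str]:
        return [self.mask.apply(r.seq) for r in self.alignment.records]


# ---------------------------------------------------------------------------
# FASTA and sample-sheet I/O


_META_TOKEN = re.compile(r"(\w+)=(\S+)")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords, order preserved, sequences uppercased.

    Header tokens of the form ``key=value`` (keys species/region/site) are
    picked up as metadata; anything else is ignored so that plain headers
    still work with a separate sample sheet.
    """
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise ValueError(f"no sequences in {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for e in entries:
        if e.id in seen:
            raise ValueError(f"duplicate sequence id: {e.id!r}")
        seen.add(e.id)
        meta = dict(_META_TOKEN.findall(e.description))
        records.append(
            SequenceRecord(
                id=e.id,
                seq=str(e.seq),
                species=meta.get("species", ""),
                region=meta.get("region", ""),
                site=meta.get("site", ""),
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA, embedding metadata as key=value tokens."""
    bio = []
    for r in records:
        desc = " ".join(
            f"{k}={v}"
            for k, v in (("species", r.species), ("region", r.region), ("site", r.site))
            if v
        )
        bio.append(_BioRecord(Seq(r.seq), id=r.id, description=desc))
    SeqIO.write(bio, str(path), "fasta")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a TSV sample sheet with columns id, species, region, site."""
    sheet = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet is missing columns: {missing}")
    dup = sheet["id"][sheet["id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate ids in sample sheet: {sorted(set(dup))}")
    return sheet


def write_sample_sheet(records: Iterable[SequenceRecord], path: str | Path) -> None:
    rows = [
        {"id": r.id, "species": r.species, "region": r.region, "site": r.site}
        for r in records
    ]
    pd.DataFrame(rows, columns=list(SAMPLE_SHEET_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def attach_metadata(records: list[SequenceRecord],
                    sheet: pd.DataFrame) -> list[SequenceRecord]:
    """Fill species/region/site from a sample sheet (sheet wins over header)."""
    lookup = sheet.set_index("id")
    out = []
    for r in records:
        if r.id in lookup.index:
            row = lookup.loc[r.id]
            out.append(SequenceRecord(r.id, r.seq, row["species"],
                                      row["region"], row["site"]))
        else:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Codon-aware quality screen


@dataclass
class QCRecord:
    id: str
    passed: bool
    reason: str = ""
    codon_index: int | None = None  # 1-based index of the offending codon


def screen_orf(aln: CodonAlignment) -> list[QCRecord]:
    """Flag putative NUMTs: frame-shifted or internally stop-containing reads.

    A record fails if (a) any internal gap run has a length that is not a
    multiple of 3 (a frame-shifting indel relative to the alignment), or
    (b) its in-frame translation under the configured genetic code contains
    a stop codon before the final codon.
    """
    codons.get_code(aln.genetic_code)  # validates the code id
    reports: list[QCRecord] = []
    for rec in aln.records:
        trimmed = rec.seq.strip("-")
        shift = next(
            (m for m in re.finditer(r"-+", trimmed) if len(m.group()) % 3),
            None,
        )
        if shift is not None:
            reports.append(QCRecord(rec.id, False, "frame shift",
                                    codon_index=None))
            continue
        stop = _internal_stop(rec.seq, aln.frame_offset, aln.genetic_code)
        if stop is not None:
            reports.append(
                QCRecord(rec.id, False, f"internal stop at codon {stop + 1}",
                         codon_index=stop + 1)
            )
        else:
            reports.append(QCRecord(rec.id, True))
    return reports


def _internal_stop(seq: str, frame_offset: int, code_id: int) -> int | None:
    """0-based index of the first internal stop codon in frame, else None.

    Codons containing gaps or ambiguity codes are skipped (they cannot be
    called); a stop in the very last complete codon of the read is treated
    as terminal and allowed.
    """
    n_codons = (len(seq) - frame_offset) // 3
    last_called = None
    first_stop = None
    for k in range(n_codons):
        codon = seq[frame_offset + 3 * k : frame_offset + 3 * k + 3]
        if set(codon) <= ACGT:
            last_called = k
            if first_stop is None and codons.is_stop(codon, code_id):
                first_stop = k
    if first_stop is not None and first_stop != last_called:
        return first_stop
    return None


def write_qc_report(reports: list[QCRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"id": r.id, "pass": int(r.passed), "reason": r.reason}
            for r in reports
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Complete-case site masks and population subsetting


def complete_sites(aln: CodonAlignment, subset: Sequence[str]) -> SiteMask:
    """Columns where every subset record has an unambiguous A/C/G/T base.

    This is the complete-case "sites used" convention of per-population
    diversity tables: gaps and ambiguity codes remove a column for the
    whole subset.
    """
    if not subset:
        raise ValueError("empty subset")
    seqs = [aln.get(i).seq for i in subset]
    used = [
        col
        for col in range(aln.length)
        if all(s[col] in ACGT for s in seqs)
    ]
    if not used:
        raise ValueError("no usable sites: every column has a gap or ambiguity")
    return SiteMask(used)


MIN_SAMPLE = 4  # estimation gate: statistics need at least 4 specimens


def subsample_population(
    aln: CodonAlignment,
    sheet: pd.DataFrame,
    species: str,
    site: str,
) -> PopulationSample:
    """Extract one (species, site) population and its complete-site mask.

    Populations with fewer than 4 specimens are returned with
    ``excluded=True``: they are reported with counts but carry no diversity
    or demography estimates.
    """
    rows = sheet[(sheet["species"] == species) & (sheet["site"] == site)]
    if rows.empty:
        raise ValueError(f"no specimens for species={species!r} site={site!r}")
    ids = [i for i in rows["id"] if i in set(aln.ids())]
    if not ids:
        raise ValueError(
            f"sample sheet ids for species={species!r} site={site!r} "
            "are absent from the alignment"
        )
    sub = aln.subset(ids)
    mask = complete_sites(aln, ids)
    region = rows["region"].iloc[0]
    return PopulationSample(
        alignment=sub,
        mask=mask,
        species=species,
        region=region,
        site=site,
        excluded=len(ids) < MIN_SAMPLE,
    )
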