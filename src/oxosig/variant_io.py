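"""Readers and writers for the formats the pipeline touches.

Somatic SNV calls come in as VCF (sites-only is fine), the reference genome as
an indexed FASTA, and copy-number (CBS), clinical and signature tables as
tab-delimited text.  Variant calling itself is upstream: this module only
loads called variants into the internal data model.

Positions are 1-based throughout, as in VCF; FASTA lookups convert
internally.  Chromosome-name dialects are normalized by stripping a
configurable prefix (default ``"chr"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from pyfaidx import Fasta

from .spectra import _BASE_CODE, CHANNELS_96

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic single-nucleotide variant (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("SomaticVariant holds single-base alleles only")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")


class MutationCatalog:
    """Per-sample set of somatic SNVs plus a small-indel count.

    Internally variants are held as a DataFrame (chrom, pos, ref, alt) so that
    spectra can be computed vectorized; ``variants`` exposes the record view.
    Duplicate (chrom, pos, ref, alt) entries are deduplicated with a warning —
    spectra count unique somatic events.
    """

    def __init__(self, sample_id: str, df: pd.DataFrame | None = None, n_indels: int = 0):
        self.sample_id = sample_id
        self.n_indels = int(n_indels)
        if df is None:
            df = pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
        df = df.reset_index(drop=True)
        df["pos"] = df["pos"].astype(np.int64)
        n0 = len(df)
        df = df.drop_duplicates(subset=["chrom", "pos", "ref", "alt"], ignore_index=True)
        if len(df) < n0:
            logger.warning(
                "%s: deduplicated %d repeated variant record(s)", sample_id, n0 - len(df)
            )
        self.df = df

    @classmethod
    def from_variants(cls, sample_id: str, variants, n_indels: int = 0) -> "MutationCatalog":
        rows = [(v.chrom, v.pos, v.ref, v.alt) for v in variants]
        df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
        return cls(sample_id, df, n_indels)

    @property
    def variants(self) -> list[SomaticVariant]:
        return [
            SomaticVariant(c, int(p), r, a, self.sample_id)
            for c, p, r, a in self.df.itertuples(index=False)
        ]

    def variant_keys(self) -> set[tuple[str, int, str, str]]:
        return {
            (c, int(p), r, a) for c, p, r, a in self.df.itertuples(index=False)
        }

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MutationCatalog)
            and self.sample_id == other.sample_id
            and self.n_indels == other.n_indels
            and self.variant_keys() == other.variant_keys()
        )


def normalize_chrom(name: str, strip_prefix: str = "chr") -> str:
    if strip_prefix and name.startswith(strip_prefix) and len(name) > len(strip_prefix):
        return name[len(strip_prefix):]
    return name


def read_snv_catalog(
    vcf_path: str | Path, sample_id: str, strip_prefix: str = "chr"
) -> MutationCatalog:
    """Load the biallelic SNVs of a VCF into a catalog.

    Multi-allelic records are split and each alternate allele classified
    independently.  Indel alleles are tallied into ``n_indels``; alleles with
    N/IUPAC-ambiguous bases or other unclassifiable shapes are skipped with a
    logged count.
    """
    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise FileNotFoundError(vcf_path)
    chroms, positions, refs, alts = [], [], [], []
    n_indels = 0
    n_skipped = 0
    for rec in VCF(str(vcf_path)):
        ref = (rec.REF or "").upper()
        for alt in rec.ALT or []:
            alt = alt.upper()
            if len(ref) == 1 and len(alt) == 1:
                if ref in _VALID and alt in _VALID and ref != alt:
                    chroms.append(normalize_chrom(rec.CHROM, strip_prefix))
                    positions.append(rec.POS)
                    refs.append(ref)
                    alts.append(alt)
                else:
                    n_skipped += 1
            elif (
                len(ref) != len(alt)
                and set(ref) <= _VALID
                and set(alt) <= _VALID
            ):
                n_indels += 1
            else:
                n_skipped += 1
    if n_skipped:
        logger.warning("%s: skipped %d unclassifiable allele(s)", vcf_path.name, n_skipped)
    df = pd.DataFrame({"chrom": chroms, "pos": positions, "ref": refs, "alt": alts})
    return MutationCatalog(sample_id, df, n_indels)


def write_snv_vcf(catalog: MutationCatalog, path: str | Path, contigs: Mapping[str, int] | None = None) -> Path:
    """Write a catalog as a minimal sites-only VCF 4.2 file."""
    path = Path(path)
    df = catalog.df.sort_values(["chrom", "pos", "ref", "alt"], kind="stable")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=oxosig\n##SAMPLE=<ID={catalog.sample_id}>\n")
        names = contigs or {c: None for c in pd.unique(df["chrom"])}
        for name, length in names.items():
            if length:
                fh.write(f"##contig=<ID={name},length={length}>\n")
            else:
                fh.write(f"##contig=<ID={name}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c, p, r, a in df.itertuples(index=False):
            fh.write(f"{c}\t{p}\t.\t{r}\t{a}\t.\tPASS\t.\n")
    return path


class ReferenceContextSource:
    """Trinucleotide-context lookups against an indexed FASTA.

    Chromosome sequences are cached as uppercase base-code arrays
    (A=0,C=1,G=2,T=3, other=4) so whole catalogs can be classified with a
    single fancy-indexing pass.
    """

    def __init__(self, fasta_path: str | Path, strip_prefix: str = "chr"):
        self.path = Path(fasta_path)
        self._fasta = Fasta(str(self.path), as_raw=True, sequence_always_upper=True)
        self.strip_prefix = strip_prefix
        self._codes_cache: dict[str, np.ndarray] = {}
        self._names = {
            normalize_chrom(name, strip_prefix): name for name in self._fasta.keys()
        }

    def _chrom_codes(self, chrom: str) -> np.ndarray:
        chrom = normalize_chrom(chrom, self.strip_prefix)
        if chrom not in self._codes_cache:
            raw = str(self._fasta[self._names[chrom]][:])
            arr = np.frombuffer(raw.encode("ascii"), dtype=np.uint8)
            codes = np.full(arr.shape, 4, dtype=np.int64)
            for base, code in _BASE_CODE.items():
                codes[arr == ord(base)] = code
            self._codes_cache[chrom] = codes
        return self._codes_cache[chrom]

    def lookup(self, chrom: str, pos: int) -> str:
        """Trinucleotide covering pos-1..pos+1 (1-based pos); raises at edges."""
        seq = str(self._fasta[self._names[normalize_chrom(chrom, self.strip_prefix)]][:])
        if pos < 2 or pos > len(seq) - 1:
            raise IndexError(f"position {chrom}:{pos} has no full trinucleotide context")
        return seq[pos - 2 : pos + 1]

    def context_codes(
        self, chroms: np.ndarray, positions: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized (left, mid, right) base codes; edge positions code 4."""
        n = len(positions)
        left = np.full(n, 4, dtype=np.int64)
        mid = np.full(n, 4, dtype=np.int64)
        right = np.full(n, 4, dtype=np.int64)
        chroms = np.asarray(chroms)
        for chrom in pd.unique(chroms):
            codes = self._chrom_codes(str(chrom))
            sel = np.flatnonzero(chroms == chrom)
            pos0 = positions[sel] - 1  # 0-based
            ok = (pos0 >= 0) & (pos0 < len(codes))
            mid[sel[ok]] = codes[pos0[ok]]
            okl = pos0 >= 1
            left[sel[okl]] = codes[pos0[okl] - 1]
            okr = pos0 <= len(codes) - 2
            right[sel[okr]] = codes[pos0[okr] + 1]
        return left, mid, right


@dataclass(frozen=True)
class GeneCBSRecord:
    """Gene-level circular-binary-segmentation log-ratio for one sample."""

    sample_id: str
    gene: str
    cbs: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.cbs):
            raise ValueError(f"non-finite CBS score for {self.sample_id}/{self.gene}")


@dataclass
class SurvivalRecord:
    """Right-censored follow-up for one sample; event 1 = death."""

    sample_id: str
    time: float
    event: int
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("follow-up time must be non-negative")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


class SchemaError(ValueError):
    """A required column is missing or a field fails to parse."""


def read_cbs_table(path: str | Path) -> list[GeneCBSRecord]:
    """Long-format table with columns sample_id, gene, cbs."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "gene", "cbs"):
        if col not in df.columns:
            raise SchemaError(f"CBS table missing required column {col!r}")
    cbs = pd.to_numeric(df["cbs"], errors="coerce")
    if cbs.isna().any():
        bad = df.loc[cbs.isna()].iloc[0]
        raise SchemaError(
            f"non-numeric cbs value {bad['cbs']!r} for sample {bad['sample_id']!r}"
        )
    return [
        GeneCBSRecord(str(s), str(g), float(v))
        for s, g, v in zip(df["sample_id"], df["gene"], cbs)
    ]


def read_clinical_table(path: str | Path) -> list[SurvivalRecord]:
    """Clinical table with columns sample_id, time, event; extras kept as covariates."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise SchemaError(f"clinical table missing required column {col!r}")
    extra = [c for c in df.columns if c not in ("sample_id", "time", "event")]
    records = []
    for _, row in df.iterrows():
        try:
            rec = SurvivalRecord(
                str(row["sample_id"]),
                float(row["time"]),
                int(row["event"]),
                {c: row[c] for c in extra},
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"bad clinical row for {row['sample_id']!r}: {exc}") from exc
        records.append(rec)
    return records


def read_signature_matrix(path: str | Path):
    """Read a COSMIC-layout SBS signature table (column ``Type``, one column
    per signature) into a :class:`~oxosig.signatures.SignatureMatrix`.

    Rows may appear in any order; they are normalized to the canonical
    96-channel order.  Missing or duplicate channels, negative entries, or a
    column not summing to 1 raise a validation error naming the offender.
    """
    from .signatures import SignatureMatrix

    df = pd.read_csv(path, sep="\t")
    type_col = "Type" if "Type" in df.columns else df.columns[0]
    df = df.set_index(type_col)
    dupes = df.index[df.index.duplicated()].tolist()
    if dupes:
        raise SchemaError(f"duplicate channel row(s): {dupes}")
    missing = [ch for ch in CHANNELS_96 if ch not in df.index]
    if missing:
        raise SchemaError(f"missing channel row(s): {missing[:5]}")
    df = df.loc[list(CHANNELS_96)]
    P = df.to_numpy(dtype=float)
    return SignatureMatrix(names=list(df.columns), P=P)


def write_signature_matrix(matrix, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(matrix.P, index=pd.Index(CHANNELS_96, name="Type"), columns=matrix.names)
    df.to_csv(path, sep="\t")
    return path
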