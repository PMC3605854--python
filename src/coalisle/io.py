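"""Readers and writers for FASTA, Genepop, population maps and run configs."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import DatasetBundle, SequenceAlignment, STRDataset

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_genepop",
    "write_genepop",
    "read_popmap",
    "write_popmap",
    "read_bundle",
]


class FormatError(ValueError):
    pass


def read_fasta(
    path, pops: Mapping[str, str] | None = None
) -> SequenceAlignment:
    """Read an aligned FASTA file; preserves record order, uppercases, and
    validates equal lengths (a ragged record raises FormatError naming it)."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        logger.warning("empty FASTA file: %s", path)
        return SequenceAlignment([], [], np.empty((0, 0), np.uint8))
    L = len(records[0][1])
    for name, seq in records:
        if len(seq) != L:
            raise FormatError(
                f"record {name!r} has length {len(seq)}, expected {L} (ragged alignment)"
            )
    return SequenceAlignment.from_strings(records, pops)


def write_fasta(aln: SequenceAlignment, path, wrap: int = 70) -> None:
    recs = [
        SeqRecord(Seq(aln.sequence(i)), id=aln.names[i], description="")
        for i in range(aln.n)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def write_genepop(ds: STRDataset, path, title: str = "coalisle STR data") -> None:
    """Write gene copies as haploid Genepop records with 3-digit alleles.

    Consecutive pairs of gene copies from the same strain are written as one
    diploid individual line when the copy count per population is even;
    otherwise copies are written one per line.
    """
    pops_order: list[str] = []
    for p in ds.pops:
        if p not in pops_order:
            pops_order.append(p)
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for name in ds.locus_names:
            fh.write(name + "\n")
        for pop in pops_order:
            mask = [i for i, p in enumerate(ds.pops) if p == pop]
            fh.write("POP\n")
            block = ds.matrix[mask]
            even = len(mask) % 2 == 0
            if even:
                for k in range(0, len(mask), 2):
                    a, b = block[k], block[k + 1]
                    genos = " ".join(
                        f"{_code(x)}{_code(y)}" for x, y in zip(a, b)
                    )
                    fh.write(f"{pop}_{k // 2:03d} , {genos}\n")
            else:
                for k in range(len(mask)):
                    genos = " ".join(f"{_code(x)}{_code(x)}" for x in block[k])
                    fh.write(f"{pop}_{k:03d} , {genos}\n")


def _code(allele: int) -> str:
    return "000" if allele < 0 else f"{int(allele):03d}"


def read_genepop(path) -> STRDataset:
    """Read a Genepop file into gene copies (two per diploid genotype).

    2- and 3-digit allele dialects are auto-detected; allele code 000 is
    recorded as missing (-1).  Population labels are taken from the first
    token of each individual's name, falling back to ``pop1``, ``pop2``...
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise FormatError("Genepop file too short")
    idx = 1
    loci: list[str] = []
    while idx < len(lines) and lines[idx].strip().upper() != "POP":
        # loci may be one per line or comma-separated
        loci += [t.strip() for t in lines[idx].split(",") if t.strip()]
        idx += 1
    if idx == len(lines):
        raise FormatError("no POP block found")
    names: list[str] = []
    pops: list[str] = []
    rows: list[list[int]] = []
    pop_counter = 0
    cur_pop = ""
    for ln_no, line in enumerate(lines[idx:], start=idx + 1):
        s = line.strip()
        if not s:
            continue
        if s.upper() == "POP":
            pop_counter += 1
            cur_pop = f"pop{pop_counter}"
            continue
        if "," not in s:
            raise FormatError(f"line {ln_no}: expected 'name , genotypes'")
        name, _, genos = s.partition(",")
        name = name.strip()
        toks = genos.split()
        if len(toks) != len(loci):
            raise FormatError(
                f"line {ln_no}: {len(toks)} genotypes for {len(loci)} loci"
            )
        # auto-detect dialect from token width: 2x2 or 2x3 digits
        width = len(toks[0]) // 2
        if width not in (2, 3) or any(len(t) != 2 * width for t in toks):
            raise FormatError(f"line {ln_no}: malformed genotype tokens")
        a_row, b_row = [], []
        for t in toks:
            a, b = int(t[:width]), int(t[width:])
            a_row.append(a if a != 0 else -1)
            b_row.append(b if b != 0 else -1)
        label = name.split("_")[0] if "_" in name else cur_pop
        names += [name + "a", name + "b"]
        pops += [label, label]
        rows += [a_row, b_row]
    if not rows:
        raise FormatError("no individuals found")
    return STRDataset(names, pops, np.asarray(rows), loci)


# ---------------------------------------------------------------------------
# Population map + bundle assembly
# ---------------------------------------------------------------------------

def write_popmap(bundle: DatasetBundle, path) -> None:
    with open(path, "w") as fh:
        fh.write("copy\tpopulation\tmarker\n")
        for n, p in zip(bundle.mt.names, bundle.mt.pops):
            fh.write(f"{n}\t{p}\tmt\n")
        for n, p in zip(bundle.strs.names, bundle.strs.pops):
            fh.write(f"{n}\t{p}\tstr\n")


def read_popmap(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or line.startswith("copy\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"popmap line {i + 1}: need 'copy<TAB>population'")
        out[parts[0]] = parts[1]
    return out


def read_bundle(fasta_path, genepop_path=None, popmap_path=None) -> DatasetBundle:
    """Assemble a DatasetBundle from on-disk files."""
    pops = read_popmap(popmap_path) if popmap_path else None
    mt = read_fasta(fasta_path, pops)
    if genepop_path:
        strs = read_genepop(genepop_path)
        if pops:
            strs.pops = [pops.get(n, p) for n, p in zip(strs.names, strs.pops)]
    else:
        strs = STRDataset([], [], np.empty((0, 0), np.int64))
    return DatasetBundle(mt=mt, strs=strs, provenance={"source": str(fasta_path)})
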