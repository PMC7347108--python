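"""File formats: SEG-like TSV profiles, BEDPE and VCF-BND junctions,
Newick lineage trees, TSV event logs, and the reproducibility manifest.

Internal coordinates are 0-based half-open; VCF positions are converted to
1-based on write and back on read.  Junction insertion chains round-trip
losslessly through both BEDPE (extra columns) and VCF (INFO keys MATEID,
INSSEQ, INSSRC, HOMCLASS, HOMLEN, INNERHOM, UNTEMPL).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import pysam

from .cascade import Lineage
from .config import CascadeConfig
from .genome import GenomeDeclaration, GenomicInterval
from .junctions import Breakend, Homology, Junction, TemplatedInsertion
from .sequencing import ObservedProfile


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# junction serialization helpers
# ---------------------------------------------------------------------------

def _enc_insertions(j: Junction) -> str:
    if not j.insertions:
        return "."
    return ",".join(
        f"{i.source.chrom}:{i.source.start}-{i.source.end}:{i.strand}:{i.source.haplotype}"
        for i in j.insertions
    )


def _dec_insertions(s: str) -> tuple[TemplatedInsertion, ...]:
    if s in (".", ""):
        return ()
    out = []
    for tok in s.split(","):
        loc, strand, hap = tok.rsplit(":", 2)
        chrom, span = loc.rsplit(":", 1)
        a, b = span.split("-")
        out.append(TemplatedInsertion(GenomicInterval(chrom, int(a), int(b), hap), strand))
    return tuple(out)


def _enc_homology(h: Homology) -> str:
    return f"{h.kind}:{h.length}"


def _dec_homology(s: str) -> Homology:
    kind, ln = s.rsplit(":", 1)
    return Homology(kind, int(ln))


def _enc_inner(j: Junction) -> str:
    if not j.inner_homology:
        return "."
    return ",".join(_enc_homology(h) for h in j.inner_homology)


def _enc_untempl(j: Junction) -> str:
    if not j.untemplated_seqs:
        return "."
    return ",".join(s if s else "-" for s in j.untemplated_seqs)


def _dec_inner(s: str) -> tuple[Homology, ...]:
    if s in (".", ""):
        return ()
    return tuple(_dec_homology(t) for t in s.split(","))


def _dec_untempl(s: str) -> tuple[str, ...]:
    if s in (".", ""):
        return ()
    return tuple("" if t == "-" else t for t in s.split(","))


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

_BEDPE_COLS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score",
    "strand1", "strand2", "hap1", "hap2", "homology", "insertions",
    "inner_homology", "untemplated",
]


def write_bedpe(path, junctions: list[Junction]) -> None:
    rows = []
    for n, j in enumerate(junctions):
        rows.append(
            dict(
                chrom1=j.bnd1.chrom, start1=j.bnd1.pos, end1=j.bnd1.pos + 1,
                chrom2=j.bnd2.chrom, start2=j.bnd2.pos, end2=j.bnd2.pos + 1,
                name=f"jx{n}", score=".", strand1=j.bnd1.orient, strand2=j.bnd2.orient,
                hap1=j.bnd1.haplotype, hap2=j.bnd2.haplotype,
                homology=_enc_homology(j.homology), insertions=_enc_insertions(j),
                inner_homology=_enc_inner(j), untemplated=_enc_untempl(j),
            )
        )
    pd.DataFrame(rows, columns=_BEDPE_COLS).to_csv(path, sep="\t", index=False)


def read_bedpe(path) -> list[Junction]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: list[Junction] = []
    for _, r in df.iterrows():
        out.append(
            Junction(
                Breakend(r["chrom1"], int(r["start1"]), r["strand1"], r["hap1"]),
                Breakend(r["chrom2"], int(r["start2"]), r["strand2"], r["hap2"]),
                _dec_insertions(r["insertions"]),
                _dec_homology(r["homology"]),
                _dec_inner(r["inner_homology"]),
                _dec_untempl(r["untemplated"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# VCF 4.2 BND
# ---------------------------------------------------------------------------

def _vcf_pos_alt(b1: Breakend, b2: Breakend) -> tuple[int, str]:
    """1-based POS and BND ALT for the record anchored at b1."""
    pos1 = b1.pos if b1.orient == "+" else b1.pos + 1
    pos2 = b2.pos if b2.orient == "+" else b2.pos + 1
    mate = f"{b2.chrom}:{pos2}"
    if b1.orient == "+":
        alt = f"N[{mate}[" if b2.orient == "-" else f"N]{mate}]"
    else:
        alt = f"]{mate}]N" if b2.orient == "+" else f"[{mate}[N"
    return pos1, alt


def _parse_alt(alt: str) -> tuple[str, int, str, str]:
    """(mate_chrom, mate_pos_1based, orient_here, orient_mate) from a BND ALT."""
    if alt.startswith("N["):
        body, o1, o2 = alt[2:-1], "+", "-"
    elif alt.startswith("N]"):
        body, o1, o2 = alt[2:-1], "+", "+"
    elif alt.startswith("]"):
        body, o1, o2 = alt[1 : alt.rindex("]")], "-", "+"
    elif alt.startswith("["):
        body, o1, o2 = alt[1 : alt.rindex("[")], "-", "-"
    else:
        raise FormatError(f"not a BND ALT: {alt!r}")
    chrom, pos = body.rsplit(":", 1)
    return chrom, int(pos), o1, o2


def write_vcf_bnd(path, junctions: list[Junction], genome: GenomeDeclaration) -> None:
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for name in genome.names():
        header.contigs.add(name, length=genome.length(name))
    for line in (
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">',
        '##INFO=<ID=INSSEQ,Number=1,Type=String,Description="Ordered templated insertion chain">',
        '##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Homology length">',
        '##INFO=<ID=HOMCLASS,Number=1,Type=String,Description="Junction homology class">',
        '##INFO=<ID=INNERHOM,Number=1,Type=String,Description="Chain join homology classes">',
        '##INFO=<ID=UNTEMPL,Number=1,Type=String,Description="Untemplated join sequences">',
        '##INFO=<ID=HAPLOTYPE,Number=1,Type=String,Description="Breakend haplotype">',
        '##INFO=<ID=MATEHAP,Number=1,Type=String,Description="Mate haplotype">',
    ):
        header.add_line(line)
    vf = pysam.VariantFile(str(path), "w", header=header)
    for n, j in enumerate(junctions):
        for tag, b_this, b_mate in (("A", j.bnd1, j.bnd2), ("B", j.bnd2, j.bnd1)):
            pos, alt = _vcf_pos_alt(b_this, b_mate)
            rec = vf.new_record(
                contig=b_this.chrom, start=max(pos - 1, 0), alleles=("N", alt),
                id=f"bnd{n}{tag}",
            )
            rec.info["SVTYPE"] = "BND"
            rec.info["MATEID"] = f"bnd{n}{'B' if tag == 'A' else 'A'}"
            rec.info["HOMCLASS"] = _enc_homology(j.homology).replace(":", "|")
            rec.info["HOMLEN"] = j.homology.length
            rec.info["HAPLOTYPE"] = b_this.haplotype
            rec.info["MATEHAP"] = b_mate.haplotype
            if tag == "A":
                # '&' separates chain members: ',' and ';' are reserved in INFO
                rec.info["INSSEQ"] = _enc_insertions(j).replace(":", "|").replace(",", "&")
                rec.info["INNERHOM"] = _enc_inner(j).replace(":", "|").replace(",", "&")
                rec.info["UNTEMPL"] = _enc_untempl(j).replace(",", "&")
        # write both records
            vf.write(rec)
    vf.close()


def read_vcf_bnd(path) -> list[Junction]:
    vf = pysam.VariantFile(str(path))
    recs = {r.id: r for r in vf}
    seen: set[str] = set()
    out: list[Junction] = []
    for rid, r in recs.items():
        if rid in seen:
            continue
        mid = r.info["MATEID"]
        seen.update({rid, mid})
        mate = recs[mid]
        chrom2, pos2_1b, o1, o2 = _parse_alt(r.alts[0])
        pos1_1b = r.pos  # pysam .pos is 1-based
        b1 = Breakend(
            r.contig, pos1_1b if o1 == "+" else pos1_1b - 1, o1, r.info["HAPLOTYPE"]
        )
        b2 = Breakend(
            chrom2, pos2_1b if o2 == "+" else pos2_1b - 1, o2, r.info["MATEHAP"]
        )
        primary = r if "INSSEQ" in r.info else mate
        if primary is not r:
            chrom2b, pos2b, o1b, o2b = _parse_alt(mate.alts[0])
            b1 = Breakend(mate.contig, mate.pos if o1b == "+" else mate.pos - 1, o1b,
                          mate.info["HAPLOTYPE"])
            b2 = Breakend(chrom2b, pos2b if o2b == "+" else pos2b - 1, o2b,
                          mate.info["MATEHAP"])
        insseq = str(primary.info.get("INSSEQ", ".")).replace("&", ",")
        inner = str(primary.info.get("INNERHOM", ".")).replace("&", ",")
        unt = str(primary.info.get("UNTEMPL", ".")).replace("&", ",")
        hom = str(primary.info.get("HOMCLASS", "blunt|0"))
        out.append(
            Junction(
                b1, b2,
                _dec_insertions(insseq.replace("|", ":")) if insseq != "." else (),
                _dec_homology(hom.replace("|", ":")),
                _dec_inner(inner.replace("|", ":")) if inner != "." else (),
                _dec_untempl(unt),
            )
        )
    for rid in recs:
        if rid not in seen:
            raise FormatError(f"unpaired BND record {rid}")
    return out


def read_write_junctions(path, junctions: list[Junction] | None = None,
                         fmt: str = "bedpe", genome: GenomeDeclaration | None = None):
    """Unified entry point: write when ``junctions`` is given, else read."""
    if fmt not in ("bedpe", "vcf"):
        raise FormatError(f"unknown junction format {fmt!r}")
    if junctions is not None:
        if fmt == "bedpe":
            write_bedpe(path, junctions)
        else:
            if genome is None:
                raise FormatError("VCF export needs a genome declaration for contigs")
            write_vcf_bnd(path, junctions, genome)
        return junctions
    return read_bedpe(path) if fmt == "bedpe" else read_vcf_bnd(path)


# ---------------------------------------------------------------------------
# SEG-like TSV profiles
# ---------------------------------------------------------------------------

def write_seg(path, profile: ObservedProfile, chunk: int = 200_000) -> None:
    """Write a binned profile as SEG-like TSV (chrom, start, end, hap, count)."""
    with open(path, "w") as fh:
        fh.write(f"#bin_size={profile.bin_size}\n")
        fh.write(f"#norm_constant={profile.norm_constant!r}\n")
        fh.write("chrom\tstart\tend\thaplotype\tcount\n")
        for (chrom, hap), arr in profile.counts.items():
            clen = profile.genome.length(chrom)
            n = len(arr)
            for lo in range(0, n, chunk):
                hi = min(lo + chunk, n)
                starts = np.arange(lo, hi) * profile.bin_size
                ends = np.minimum(starts + profile.bin_size, clen)
                block = pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": ends,
                     "haplotype": hap, "count": arr[lo:hi]}
                )
                block.to_csv(fh, sep="\t", index=False, header=False)


def read_seg(path, genome: GenomeDeclaration, chunk: int = 200_000) -> ObservedProfile:
    """Stream a SEG TSV back into an ObservedProfile without loading it whole.

    Chromosome-haplotype pairs absent from the file stay absent (CN-absent is
    distinct from CN-0).  Overlapping bins raise.
    """
    bin_size, norm = None, 1.0
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line or not line.startswith("#"):
                break
            if line.startswith("#bin_size="):
                bin_size = int(line.strip().split("=", 1)[1])
            elif line.startswith("#norm_constant="):
                norm = float(line.strip().split("=", 1)[1])
    if bin_size is None:
        raise FormatError("missing #bin_size header")
    counts: dict[tuple[str, str], np.ndarray] = {}
    filled: dict[tuple[str, str], np.ndarray] = {}
    reader = pd.read_csv(path, sep="\t", comment="#", chunksize=chunk)
    for block in reader:
        for (chrom, hap), grp in block.groupby(["chrom", "haplotype"], sort=False):
            key = (chrom, hap)
            if key not in counts:
                nb = -(-genome.length(chrom) // bin_size)
                counts[key] = np.zeros(nb, dtype=float)
                filled[key] = np.zeros(nb, dtype=bool)
            idx = grp["start"].to_numpy() // bin_size
            if filled[key][idx].any() or len(np.unique(idx)) != len(idx):
                raise FormatError(f"overlapping bins for {key}")
            counts[key][idx] = grp["count"].to_numpy(dtype=float)
            filled[key][idx] = True
    return ObservedProfile(genome, bin_size, counts, norm)


def write_cn_matrix(path, matrix: np.ndarray, cell_ids: list, columns: list) -> None:
    cols = [f"{c}:{h}:{b}" for c, h, b in columns]
    pd.DataFrame(matrix, index=cell_ids, columns=cols).to_csv(path, sep="\t")


def read_cn_matrix(path) -> tuple[np.ndarray, list[str], list[tuple[str, str, int]]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    columns = []
    for c in df.columns:
        chrom, hap, b = c.rsplit(":", 2)
        columns.append((chrom, hap, int(b)))
    return df.to_numpy(dtype=float), [str(i) for i in df.index], columns


# ---------------------------------------------------------------------------
# event log + newick
# ---------------------------------------------------------------------------

def write_event_log(path, lineage: Lineage) -> None:
    rows = [
        dict(event_id=e.event_id, generation=e.generation, cell_id=e.cell_id,
             etype=e.etype, payload=json.dumps(e.payload, sort_keys=True))
        for e in lineage.events
    ]
    pd.DataFrame(rows, columns=["event_id", "generation", "cell_id", "etype", "payload"]).to_csv(
        path, sep="\t", index=False
    )


def lineage_newick(lineage: Lineage) -> str:
    def rec(cid: str) -> str:
        kids = lineage.children.get(cid, [])
        if not kids:
            return cid
        return "(" + ",".join(rec(k) for k in kids) + ")" + cid

    return rec(lineage.root.cell_id) + ";"


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance of one pipeline run: config hash, seed, file inventory."""

    config_hash: str
    seed: int
    version: str
    files: dict[str, str] = field(default_factory=dict)
    timestamp: str = ""

    @staticmethod
    def sha256(path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for block in iter(lambda: fh.read(1 << 20), b""):
                h.update(block)
        return h.hexdigest()

    @classmethod
    def create(cls, config: CascadeConfig, seed: int, files: dict[str, str],
               version: str) -> "RunManifest":
        cfg = hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()
        return cls(cfg, seed, version,
                   {name: cls.sha256(p) for name, p in files.items()},
                   time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))

    def matches(self, other: "RunManifest") -> bool:
        """Byte-identical outputs, ignoring timestamps."""
        return (
            self.config_hash == other.config_hash
            and self.seed == other.seed
            and self.files == other.files
        )
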