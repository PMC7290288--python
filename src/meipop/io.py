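"""Readers and writers for the caller-dialect VCF and panel TSV formats,
plus positional intersection of two call sets.

The VCF dialect is the one emitted by split-read MEI callers: symbolic
``<INS:ME:*>`` alternate alleles, ``MEINFO=subfamily,start,end,polarity``,
``TSD`` holding the duplicated sequence (or ``null``), and an integer
``ASSESS`` evidence tier.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .model import MEIError, MEICallSet, MEILocus, MISSING, SamplePanel

_ALT_TO_CLASS = {"ALU": "ALU", "LINE1": "LINE1", "L1": "LINE1", "SVA": "SVA"}


class VCFParseError(MEIError):
    """Raised when a VCF record cannot be interpreted."""


def _class_from_alt(alt: str) -> str | None:
    # symbolic alleles look like <INS:ME:ALU>
    inner = alt.strip("<>")
    parts = inner.split(":")
    if len(parts) >= 3 and parts[0] == "INS" and parts[1] == "ME":
        return _ALT_TO_CLASS.get(parts[2].upper())
    return None


def _dosage(gt: tuple | None) -> int:
    if gt is None or any(a is None for a in gt):
        return MISSING
    return int(sum(1 for a in gt if a != 0))


def read_mei_vcf(path: str | os.PathLike) -> MEICallSet:
    """Read a MEI call set from a caller-dialect VCF.

    Genotypes ``./.``, ``0/0``, ``0/1``, ``1/1`` map to missing/0/1/2;
    phased separators are accepted and collapsed to dosage.  A subfamily
    that cannot be parsed from ``MEINFO`` becomes ``"indeterminate"``.
    Non-PASS records are retained (filtering is a separate QC stage).
    """
    vcf = pysam.VariantFile(os.fspath(path))
    if "GT" not in vcf.header.formats:
        raise VCFParseError(f"{path}: no GT field defined in FORMAT header")
    samples = list(vcf.header.samples)
    loci: list[MEILocus] = []
    rows: list[list[int]] = []
    for i, rec in enumerate(vcf, start=1):
        try:
            loci.append(_locus_from_record(rec))
            rows.append([_dosage(rec.samples[s].get("GT")) for s in samples])
        except VCFParseError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise VCFParseError(f"{path}: malformed record #{i}: {exc}") from exc
    geno = np.array(rows, dtype=np.int8) if rows else np.empty((0, len(samples)), np.int8)
    return MEICallSet(loci=loci, samples=samples, genotypes=geno)


def _locus_from_record(rec: pysam.VariantRecord) -> MEILocus:
    me_class = None
    for alt in rec.alts or ():
        me_class = _class_from_alt(alt)
        if me_class:
            break
    subfamily = "indeterminate"
    orientation = "+"
    meinfo = rec.info.get("MEINFO")
    if meinfo is not None:
        if isinstance(meinfo, (tuple, list)):
            fields = [str(f) for f in meinfo]
        else:
            fields = str(meinfo).split(",")
        if fields and fields[0] not in ("", ".", "null"):
            subfamily = fields[0]
        if len(fields) >= 4 and fields[3] in ("+", "-"):
            orientation = fields[3]
        if me_class is None and subfamily != "indeterminate":
            up = subfamily.upper()
            if up.startswith("ALU"):
                me_class = "ALU"
            elif up.startswith(("L1", "LINE")):
                me_class = "LINE1"
            elif up.startswith("SVA"):
                me_class = "SVA"
    if me_class is None:
        raise VCFParseError(
            f"{rec.chrom}:{rec.pos}: cannot determine MEI class from ALT/MEINFO"
        )
    tsd = rec.info.get("TSD")
    if isinstance(tsd, (tuple, list)):
        tsd = tsd[0] if tsd else None
    tsd_len = 0 if tsd in (None, "null", ".", "") else len(str(tsd))
    assess = int(rec.info.get("ASSESS", 0))
    filters = list(rec.filter.keys())
    filter_status = "PASS" if filters in ([], ["PASS"]) else ";".join(filters)
    return MEILocus(
        chrom=rec.chrom,
        pos=rec.pos,
        me_class=me_class,
        subfamily=subfamily,
        orientation=orientation,
        tsd_len=tsd_len,
        assess=assess,
        filter_status=filter_status,
    )


def write_mei_vcf(calls: MEICallSet, path: str | os.PathLike) -> None:
    """Write a call set back to the same VCF dialect (lossless round trip)."""
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    for chrom in dict.fromkeys(l.chrom for l in calls.loci):
        header.add_line(f"##contig=<ID={chrom}>")
    header.add_line(
        '##INFO=<ID=MEINFO,Number=4,Type=String,'
        'Description="Mobile element info of the form NAME,START,END,POLARITY">'
    )
    header.add_line(
        '##INFO=<ID=TSD,Number=1,Type=String,'
        'Description="Target site duplication sequence, or null">'
    )
    header.add_line(
        '##INFO=<ID=ASSESS,Number=1,Type=Integer,Description="Evidence tier 0-5">'
    )
    for status in dict.fromkeys(l.filter_status for l in calls.loci):
        if status != "PASS":
            for name in status.split(";"):
                if name not in header.filters:
                    header.add_line(f'##FILTER=<ID={name},Description="Non-pass">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in calls.samples:
        header.add_sample(s)
    alt_of = {"ALU": "<INS:ME:ALU>", "LINE1": "<INS:ME:LINE1>", "SVA": "<INS:ME:SVA>"}
    gt_of = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for i, locus in enumerate(calls.loci):
            rec = out.new_record(
                contig=locus.chrom,
                start=locus.pos - 1,
                stop=locus.pos,
                alleles=("N", alt_of[locus.me_class]),
            )
            rec.info["MEINFO"] = (
                locus.subfamily,
                "1",
                "1",
                locus.orientation,
            )
            rec.info["TSD"] = "N" * locus.tsd_len if locus.tsd_len else "null"
            rec.info["ASSESS"] = locus.assess
            if locus.filter_status == "PASS":
                rec.filter.add("PASS")
            else:
                for name in locus.filter_status.split(";"):
                    rec.filter.add(name)
            for j, s in enumerate(calls.samples):
                rec.samples[s]["GT"] = gt_of[int(calls.genotypes[i, j])]
            out.write(rec)


def read_sample_panel(path: str | os.PathLike) -> SamplePanel:
    """Read sample metadata TSV (sample, population, group, lat, lon)."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample": str})
    return SamplePanel(frame)


def write_sample_panel(panel: SamplePanel, path: str | os.PathLike) -> None:
    panel.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Call-set intersection


@dataclass
class IntersectionResult:
    """One-to-one positional matching between two call sets.

    ``matched`` has columns ``index_a``, ``index_b``, ``distance``.
    ``unmatched_a``/``unmatched_b`` are locus indices with no partner.
    """

    matched: pd.DataFrame
    unmatched_a: list[int]
    unmatched_b: list[int]

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def _check_sorted(calls: MEICallSet, name: str) -> None:
    keys = [(l.chrom, l.pos) for l in calls.loci]
    if keys != sorted(keys):
        raise MEIError(
            f"call set {name!r} is not sorted by chrom,pos; sort before intersecting"
        )


def intersect_callsets(
    a: MEICallSet, b: MEICallSet, window: int = 25
) -> IntersectionResult:
    """Match loci of ``a`` against ``b`` within a +/- ``window`` bp window.

    A locus in ``a`` matches a locus in ``b`` iff chromosome and MEI class
    agree and the positions differ by at most ``window`` bp.  Matching is
    one-to-one: candidate pairs are taken nearest-first, ties broken by
    the lower coordinate pair, so each locus gets at most one partner.
    """
    if window < 0:
        raise MEIError("window must be >= 0")
    _check_sorted(a, "a")
    _check_sorted(b, "b")
    b_index: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for j, locus in enumerate(b.loci):
        b_index.setdefault((locus.chrom, locus.me_class), []).append((locus.pos, j))
    candidates: list[tuple[int, int, int, int, int]] = []
    for i, locus in enumerate(a.loci):
        near = b_index.get((locus.chrom, locus.me_class), [])
        positions = np.array([p for p, _ in near])
        if positions.size == 0:
            continue
        lo = np.searchsorted(positions, locus.pos - window, side="left")
        hi = np.searchsorted(positions, locus.pos + window, side="right")
        for p, j in near[lo:hi]:
            candidates.append((abs(p - locus.pos), locus.pos, p, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int, int]] = []
    for dist, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j, dist))
    pairs.sort()
    matched = pd.DataFrame(pairs, columns=["index_a", "index_b", "distance"])
    return IntersectionResult(
        matched=matched,
        unmatched_a=[i for i in range(a.n_loci) if i not in used_a],
        unmatched_b=[j for j in range(b.n_loci) if j not in used_b],
    )


def novel_mask(result: IntersectionResult, n_loci: int) -> np.ndarray:
    """Boolean per-locus flag for loci of ``a`` absent from the comparison set."""
    mask = np.ones(n_loci, dtype=bool)
    mask[result.matched["index_a"].to_numpy()] = False
    return mask
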