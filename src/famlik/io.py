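"""File formats: count tables, pedigree tabulation, result serialization.

The canonical interchange is a TSV of per-SNP genotype-combination counts
with header ``snp_id  structure  cell  count``; cell labels must follow the
frozen orderings documented in :mod:`famlik.tables`.  A PED/MAP convenience
layer tabulates nuclear families into these counts.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .fit import FitResult
from .tables import STRUCTURE_KINDS, StructureCounts, cell_labels

__all__ = ["read_counts", "write_counts", "tabulate_pedigree",
           "results_to_frame", "CountsParseError"]

logger = logging.getLogger("famlik")

_HEADER = ("snp_id", "structure", "cell", "count")


class CountsParseError(ValueError):
    """Malformed counts file; the message carries the offending line number."""


def write_counts(data: list[StructureCounts], path: str | Path) -> None:
    """Write count tables as TSV in the frozen cell order."""
    with open(path, "w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for ds in data:
            for lab, n in zip(cell_labels(ds.structure_kind), ds.counts):
                fh.write(f"{ds.snp_id}\t{ds.structure_kind}\t{lab}\t{int(n)}\n")


def read_counts(path: str | Path) -> list[StructureCounts]:
    """Read count tables written by :func:`write_counts`.

    Rows of one (snp, structure) block may appear in any order; every cell of
    the structure must be present exactly once.
    """
    blocks: dict[tuple[str, str], dict[str, int]] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _HEADER:
            raise CountsParseError(
                f"line 1: expected header {' '.join(_HEADER)!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise CountsParseError(f"line {lineno}: expected 4 columns")
            snp, structure, cell, count = parts
            if structure not in STRUCTURE_KINDS:
                raise CountsParseError(
                    f"line {lineno}: unknown structure {structure!r}")
            if cell not in cell_labels(structure):
                raise CountsParseError(
                    f"line {lineno}: unknown cell {cell!r} for {structure}")
            try:
                n = int(count)
            except ValueError:
                raise CountsParseError(f"line {lineno}: count {count!r} "
                                       "is not an integer") from None
            if n < 0:
                raise CountsParseError(f"line {lineno}: negative count {n}")
            key = (snp, structure)
            if key not in blocks:
                blocks[key] = {}
                order.append(key)
            if cell in blocks[key]:
                raise CountsParseError(
                    f"line {lineno}: duplicate cell {cell!r} for {key}")
            blocks[key][cell] = n
    out = []
    for snp, structure in order:
        labels = cell_labels(structure)
        cells = blocks[(snp, structure)]
        missing = set(labels) - set(cells)
        if missing:
            raise CountsParseError(
                f"incomplete block ({snp}, {structure}): missing {sorted(missing)}")
        counts = np.array([cells[lab] for lab in labels], dtype=np.int64)
        out.append(StructureCounts(structure_kind=structure, counts=counts,
                                   snp_id=snp))
    return out


# ---------------------------------------------------------------------------
# PED/MAP tabulation
# ---------------------------------------------------------------------------

def _geno_code(a1: str, a2: str, risk_allele: str) -> int | None:
    """Copies of the risk allele, or None when either allele is missing."""
    if a1 == "0" or a2 == "0":
        return None
    return int(a1 == risk_allele) + int(a2 == risk_allele)


def tabulate_pedigree(ped_path: str | Path, map_path: str | Path,
                      snp_id: str, risk_allele: str = "2"
                      ) -> list[StructureCounts]:
    """Tabulate a PED/MAP pedigree file into structure counts for one SNP.

    PED columns: family, individual, father, mother, sex, phenotype
    (1 = unaffected/control, 2 = affected, 0/-9 = unknown, treated as
    population control), then two allele columns per MAP SNP.  Each family
    contributes to exactly one structure, determined by which members are
    genotyped and the offspring's phenotype; Mendelian-inconsistent families
    are excluded with a logged report.
    """
    snps = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise CountsParseError(f"{map_path}: line {lineno}: "
                                       "expected at least 2 columns")
            snps.append(parts[1])
    if snp_id not in snps:
        raise ValueError(f"SNP {snp_id!r} not present in {map_path}")
    snp_idx = snps.index(snp_id)

    people: dict[tuple[str, str], dict] = {}
    families: dict[str, list] = {}
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6 + 2 * len(snps):
                raise CountsParseError(
                    f"{ped_path}: line {lineno}: expected "
                    f"{6 + 2 * len(snps)} columns, got {len(parts)}")
            fam, iid, fid, mid, _sex, pheno = parts[:6]
            a1, a2 = parts[6 + 2 * snp_idx: 8 + 2 * snp_idx]
            rec = {"iid": iid, "father": fid, "mother": mid, "pheno": pheno,
                   "geno": _geno_code(a1, a2, risk_allele)}
            people[(fam, iid)] = rec
            families.setdefault(fam, []).append(rec)

    tallies: dict[str, np.ndarray] = {}

    def add(structure: str, cell: str) -> None:
        labels = cell_labels(structure)
        tallies.setdefault(structure, np.zeros(len(labels), dtype=np.int64))
        tallies[structure][labels.index(cell)] += 1

    geno_str = {0: "11", 1: "12", 2: "22"}
    for fam, members in families.items():
        offspring = [m for m in members
                     if m["father"] != "0" or m["mother"] != "0"]
        if not offspring:
            # founders only: a lone genotyped individual is a control sample;
            # a genotyped pair is ambiguous without an offspring and skipped
            typed = [m for m in members if m["geno"] is not None]
            if len(typed) == 1 and typed[0]["pheno"] != "2":
                add("control", f"c{geno_str[typed[0]['geno']]}")
            elif typed:
                logger.warning("family %s: founders without offspring; "
                               "skipped", fam)
            continue
        if len(offspring) > 1:
            logger.warning("family %s: multiple offspring; using the first",
                           fam)
        child = offspring[0]
        mother = people.get((fam, child["mother"]))
        father = people.get((fam, child["father"]))
        gc = child["geno"]
        gm = mother["geno"] if mother else None
        gf = father["geno"] if father else None
        affected = child["pheno"] == "2"
        if gc is None:
            if gm is not None and gf is not None:
                add("parents_of_case" if affected else "parents_of_control",
                    _mating_label(gm, gf))
            continue
        if gm is not None and gf is not None:
            if not _mendel_ok(gm, gf, gc):
                logger.warning("family %s: Mendelian inconsistency; excluded",
                               fam)
                continue
            if affected:
                add("case_parent_trio", _trio_label(gm, gf, gc))
            else:
                # population-control trio: retain the duo information
                add("control_mother_duo", f"m{geno_str[gm]}_c{geno_str[gc]}")
            continue
        if gm is not None:
            if not _pair_ok(gm, gc):
                logger.warning("family %s: Mendelian inconsistency; excluded",
                               fam)
                continue
            add("case_mother_duo" if affected else "control_mother_duo",
                f"m{geno_str[gm]}_c{geno_str[gc]}")
            continue
        if gf is not None:
            if not _pair_ok(gf, gc):
                logger.warning("family %s: Mendelian inconsistency; excluded",
                               fam)
                continue
            add("case_father_duo" if affected else "control_father_duo",
                f"f{geno_str[gf]}_c{geno_str[gc]}")
            continue
        add("case_only" if affected else "control", f"c{geno_str[gc]}")

    return [StructureCounts(structure_kind=k, counts=v, snp_id=snp_id)
            for k, v in sorted(tallies.items())]


def _mating_label(gm: int, gf: int) -> str:
    g = {0: "11", 1: "12", 2: "22"}
    hi, lo = max(gm, gf), min(gm, gf)
    return f"{g[hi]}x{g[lo]}"


def _pair_ok(g_parent: int, g_child: int) -> bool:
    return not ((g_parent == 0 and g_child == 2)
                or (g_parent == 2 and g_child == 0))


def _mendel_ok(gm: int, gf: int, gc: int) -> bool:
    # child must receive one allele from each parent
    mat = {0: {0}, 1: {0, 1}, 2: {1}}[gm]
    pat = {0: {0}, 1: {0, 1}, 2: {1}}[gf]
    return any(a + b == gc for a in mat for b in pat)


def _trio_label(gm: int, gf: int, gc: int) -> str:
    # Table row index 1-15 from the (g_m, g_f, unordered g_c) combination
    combo = {
        (2, 2, 2): "1", (2, 1, 2): "2", (2, 1, 1): "3", (1, 2, 2): "4",
        (1, 2, 1): "5", (2, 0, 1): "6", (0, 2, 1): "7", (1, 1, 2): "8",
        (1, 1, 1): "9", (1, 1, 0): "10", (1, 0, 1): "11", (1, 0, 0): "12",
        (0, 1, 1): "13", (0, 1, 0): "14", (0, 0, 0): "15",
    }
    return combo[(gm, gf, gc)]


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def results_to_frame(results: list[tuple[str, str, FitResult]]) -> pd.DataFrame:
    """Flatten fits into the one-row-per-SNP-x-model-x-parameter result table."""
    rows = []
    for snp_id, model_name, fr in results:
        stat = max(0.0, 2.0 * (fr.max_loglik - fr.null_loglik))
        df = len(fr.spec.free_risk)
        from scipy.stats import chi2
        p = float(chi2.sf(stat, df)) if df else 1.0
        flags = []
        if not fr.converged:
            flags.append("non-converged")
        if not fr.identifiable:
            flags.append("non-identifiable")
        for name, est in fr.estimates.items():
            rows.append({
                "snp_id": snp_id, "model_name": model_name, "parameter": name,
                "estimate": est.value, "se": est.se,
                "loglik_null": fr.null_loglik, "loglik_max": fr.max_loglik,
                "lrt": stat, "df": df, "p": p,
                "flags": ";".join(flags) or "ok",
            })
    return pd.DataFrame(rows)
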