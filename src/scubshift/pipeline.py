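"""End-to-end analysis: overall, partitioned, indel-region, methylation and
allelic-group/sub-genome SCUB comparisons between a recipient and a hybrid
CDS collection, emitted as recomputable TSV tables plus a JSON summary.

Every table carries the raw counts next to each ratio and p-value, so each
statistic can be recomputed from the TSV alone.  Region analysis is skipped
cleanly when no alignments are configured; all other stages are unaffected.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .codons import (
    STANDARD_CODE,
    CodonCounts,
    EndingFrequencies,
    cg_to_at_ratio,
    extract_codons,
    per_aa_ending_counts,
    per_aa_scub_frequency,
)
from .indels import RegionClass, classify_region_codons, region_codon_counts
from .io import read_aligned_fasta, read_cds_fasta, write_tsv
from .methylation import (
    AG_PAIR_AMINO_ACIDS,
    ALT_FAMILY,
    BoundaryPairCounts,
    cross_sample_ratio,
    per_aa_ag_pair_counts,
    signature_tables,
)
from .partitions import (
    DEFAULT_INTROGRESSED,
    load_chromosome_map,
    partition_counts,
    partition_ids,
)
from .stats import (
    DegenerateTableError,
    chi_square_cross_table,
    coefficient_of_variation,
    cronbach_alpha,
    two_sample_t_test,
)

logger = logging.getLogger(__name__)

#: amino acids whose A/G codon pair has C at the second position (CpG context)
CPG_PAIR_AMINO_ACIDS = ("A", "P", "S", "T")


class PipelineConfigError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    recipient_fasta: str
    hybrid_fasta: str
    out_dir: str
    aligned_fasta: Optional[str] = None
    chromosome_map: Optional[str] = None
    introgressed_chromosomes: List[str] = field(
        default_factory=lambda: sorted(DEFAULT_INTROGRESSED)
    )
    seed: int = 0
    yates_correction: bool = False
    equal_variance_t: bool = False
    frame_offset: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def canonical(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


def _chi2_row(table, correction=False) -> dict:
    """chi-square columns for a report row; NaN p on degenerate tables."""
    try:
        res = chi_square_cross_table(table, correction=correction)
        return {
            "chi2": res.statistic,
            "df": res.df,
            "p": res.p_value,
            "min_expected": res.min_expected,
        }
    except DegenerateTableError:
        return {"chi2": np.nan, "df": np.nan, "p": np.nan, "min_expected": np.nan}


def _ratio(num: float, den: float) -> float:
    return num / den if den else np.nan


def _opt(x: Optional[float]) -> float:
    return np.nan if x is None else x


class _TestCounter:
    def __init__(self) -> None:
        self.n = 0

    def count(self, row: dict) -> dict:
        if not np.isnan(row.get("p", np.nan)):
            self.n += 1
        return row


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every configured stage and write the report bundle to out_dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    code = STANDARD_CODE
    tests = _TestCounter()

    recipient = read_cds_fasta(
        config.recipient_fasta, sample="recipient", frame_offset=config.frame_offset
    )
    hybrid = read_cds_fasta(
        config.hybrid_fasta, sample="hybrid", frame_offset=config.frame_offset
    )
    if not recipient or not hybrid:
        raise PipelineConfigError("empty recipient or hybrid FASTA")

    codons_by: Dict[str, Dict[str, list]] = {}
    counts_by: Dict[str, Dict[str, CodonCounts]] = {}
    bp_by: Dict[str, Dict[str, BoundaryPairCounts]] = {}
    for sample, records in (("recipient", recipient), ("hybrid", hybrid)):
        codons_by[sample] = {r.id: extract_codons(r) for r in records}
        counts_by[sample] = {
            rid: CodonCounts.from_codons(cods, code=code)
            for rid, cods in codons_by[sample].items()
        }
        bp_by[sample] = {
            rid: BoundaryPairCounts.from_codons(cods, code=code)
            for rid, cods in codons_by[sample].items()
        }

    assignments = {}
    if config.chromosome_map:
        assignments = load_chromosome_map(
            config.chromosome_map, introgressed_set=config.introgressed_chromosomes
        )

    schemes = ["all"]
    if assignments:
        schemes += ["mapped", "introgression", "allelic_group", "subgenome"]

    def partition_label(scheme: str, label: str) -> str:
        if scheme in ("all", "mapped", "introgression"):
            return label
        if scheme == "allelic_group":
            return f"group_{label}"
        return f"subgenome_{label}"

    # pooled counts/boundary-pairs per partition label, per sample
    pooled: Dict[str, Dict[str, CodonCounts]] = {"recipient": {}, "hybrid": {}}
    pooled_bp: Dict[str, Dict[str, BoundaryPairCounts]] = {"recipient": {}, "hybrid": {}}
    label_order: List[str] = []
    for scheme in schemes:
        for sample in ("recipient", "hybrid"):
            parts = partition_counts(counts_by[sample], assignments, scheme)
            ids = partition_ids(sorted(counts_by[sample]), assignments, scheme)
            for raw_label in sorted(parts):
                label = partition_label(scheme, raw_label)
                pooled[sample][label] = parts[raw_label]
                bp = BoundaryPairCounts()
                for rid in ids[raw_label]:
                    bp = bp + bp_by[sample][rid]
                pooled_bp[sample][label] = bp
                if sample == "recipient" and label not in label_order:
                    label_order.append(label)

    aa_list = sorted(code.sc_amino_acids)

    # ---- stage 1/2/5: per-amino-acid and total ending tables per partition
    per_aa_rows = []
    ending_rows = []
    ending_test_rows = []
    per_aa_ratio: Dict[str, Dict[str, Dict[str, Optional[float]]]] = {
        "recipient": {}, "hybrid": {}
    }
    for label in label_order:
        cc_r = pooled["recipient"][label]
        cc_h = pooled["hybrid"][label]
        per_aa_ratio["recipient"][label] = {}
        per_aa_ratio["hybrid"][label] = {}
        for aa in aa_list:
            er = per_aa_ending_counts(cc_r, aa, code)
            eh = per_aa_ending_counts(cc_h, aa, code)
            rr = per_aa_scub_frequency(cc_r, aa, code)
            rh = per_aa_scub_frequency(cc_h, aa, code)
            per_aa_ratio["recipient"][label][aa] = rr
            per_aa_ratio["hybrid"][label][aa] = rh
            row = {
                "partition": label,
                "amino_acid": aa,
                "n_AT_recipient": er["n_AT"],
                "n_CG_recipient": er["n_CG"],
                "ratio_recipient": _opt(rr),
                "n_AT_hybrid": eh["n_AT"],
                "n_CG_hybrid": eh["n_CG"],
                "ratio_hybrid": _opt(rh),
            }
            row.update(
                tests.count(
                    _chi2_row(
                        [[er["n_AT"], er["n_CG"]], [eh["n_AT"], eh["n_CG"]]],
                        config.yates_correction,
                    )
                )
            )
            per_aa_rows.append(row)

        freqs = {}
        for sample, cc in (("recipient", cc_r), ("hybrid", cc_h)):
            if cc.n_sc(code) == 0:
                freqs[sample] = None
                continue
            ef = EndingFrequencies.from_counts(cc, code)
            freqs[sample] = ef
            row = {"sample": sample, "partition": label}
            row.update(ef.as_row())
            row["cg_to_at"] = _opt(cg_to_at_ratio(cc, code))
            ending_rows.append(row)
        if freqs["recipient"] is not None and freqs["hybrid"] is not None:
            er, eh = freqs["recipient"], freqs["hybrid"]
            table = [
                [er.n_A, er.n_T, er.n_C, er.n_G],
                [eh.n_A, eh.n_T, eh.n_C, eh.n_G],
            ]
            trow = {"partition": label}
            overall = tests.count(_chi2_row(table, config.yates_correction))
            trow.update({f"{k}_overall": v for k, v in overall.items()})
            for i, base in enumerate("ATCG"):
                sub = [
                    [table[0][i], sum(table[0]) - table[0][i]],
                    [table[1][i], sum(table[1]) - table[1][i]],
                ]
                res = tests.count(_chi2_row(sub, config.yates_correction))
                trow[f"chi2_{base}"] = res["chi2"]
                trow[f"p_{base}"] = res["p"]
            cg_table = [
                [er.n_C + er.n_G, er.n_A + er.n_T],
                [eh.n_C + eh.n_G, eh.n_A + eh.n_T],
            ]
            res = tests.count(_chi2_row(cg_table, config.yates_correction))
            trow["chi2_cg_to_at"] = res["chi2"]
            trow["p_cg_to_at"] = res["p"]
            ending_test_rows.append(trow)

    write_tsv(pd.DataFrame(per_aa_rows), out_dir / "per_aa_scub.tsv")
    write_tsv(pd.DataFrame(ending_rows), out_dir / "ending_frequencies.tsv")
    write_tsv(pd.DataFrame(ending_test_rows), out_dir / "ending_tests.tsv")

    # ---- cross-partition consistency (CV across partitions, Cronbach alpha)
    consistency_rows = []
    alpha_rows = []
    consistency_sets = {}
    if assignments:
        consistency_sets["introgression"] = [
            "all", "mapped", "introgressed", "non_introgressed"
        ]
        consistency_sets["allelic_group"] = [f"group_{g}" for g in range(1, 8)]
        consistency_sets["subgenome"] = [f"subgenome_{s}" for s in "ABD"]
    for scheme_name, labels in consistency_sets.items():
        labels = [l for l in labels if l in label_order]
        for sample in ("recipient", "hybrid"):
            matrix = []
            usable_aa = []
            for aa in aa_list:
                vals = [per_aa_ratio[sample][l][aa] for l in labels]
                if any(v is None for v in vals):
                    logger.warning(
                        "skipping %s in %s consistency (undefined ratio)", aa, scheme_name
                    )
                    continue
                usable_aa.append(aa)
                matrix.append(vals)
            if not usable_aa:
                continue
            m = np.array(matrix)  # aa x partitions
            for aa, vals in zip(usable_aa, m):
                consistency_rows.append(
                    {
                        "sample": sample,
                        "scheme": scheme_name,
                        "amino_acid": aa,
                        "n_partitions": len(labels),
                        "cv": _opt(coefficient_of_variation(vals)),
                    }
                )
            alpha = cronbach_alpha(m.T)  # items = partitions, cases = amino acids
            alpha_rows.append(
                {
                    "sample": sample,
                    "scheme": scheme_name,
                    "n_items": len(labels),
                    "n_cases": len(usable_aa),
                    "cronbach_alpha": _opt(alpha),
                }
            )
    if consistency_rows:
        write_tsv(pd.DataFrame(consistency_rows), out_dir / "consistency_cv.tsv")
        write_tsv(pd.DataFrame(alpha_rows), out_dir / "consistency_alpha.tsv")

    # ---- stage 3: indel-region SCUB
    region_summary = {}
    if config.aligned_fasta:
        alignments = read_aligned_fasta(config.aligned_fasta)
        if not alignments:
            raise PipelineConfigError(
                "region stage requested but aligned FASTA is empty"
            )
        region_codons = classify_region_codons(alignments)
        side_sample = {"a": "recipient", "b": "hybrid"}
        region_rows = []
        region_counts = {}
        region_bp = {}
        for side, sample in side_sample.items():
            rcounts = region_codon_counts(region_codons[side], code)
            region_counts[sample] = rcounts
            region_bp[sample] = {}
            for rc in RegionClass:
                bp = BoundaryPairCounts()
                for codon_list in region_codons[side].per_record[rc]:
                    bp = bp + BoundaryPairCounts.from_codons(codon_list, code)
                region_bp[sample][rc] = bp
                cc = rcounts[rc]
                if cc.n_sc(code) == 0:
                    continue
                ef = EndingFrequencies.from_counts(cc, code)
                row = {"sample": sample, "region": rc.value}
                row.update(ef.as_row())
                row["cg_to_at"] = _opt(cg_to_at_ratio(cc, code))
                region_rows.append(row)
        write_tsv(pd.DataFrame(region_rows), out_dir / "region_frequencies.tsv")

        def _region_table(sample, rc):
            cc = region_counts[sample][rc]
            if cc.n_sc(code) == 0:
                return None
            ef = EndingFrequencies.from_counts(cc, code)
            return [ef.n_A, ef.n_T, ef.n_C, ef.n_G]

        region_test_rows = []
        comparisons = []
        for rc in RegionClass:
            comparisons.append(("cross_sample", rc, rc, "recipient", "hybrid"))
        for sample in ("recipient", "hybrid"):
            for rc1, rc2 in [
                (RegionClass.WHOLE, RegionClass.TWO_SIDES),
                (RegionClass.WHOLE, RegionClass.REMOTE),
                (RegionClass.REMOTE, RegionClass.TWO_SIDES),
                (RegionClass.REMOTE, RegionClass.FLANK5),
                (RegionClass.REMOTE, RegionClass.FLANK3),
                (RegionClass.FLANK5, RegionClass.FLANK3),
            ]:
                comparisons.append((sample, rc1, rc2, sample, sample))
        for name, rc1, rc2, s1, s2 in comparisons:
            row1 = _region_table(s1, rc1)
            row2 = _region_table(s2, rc2)
            if row1 is None or row2 is None:
                continue
            row = {
                "comparison": name,
                "sample_1": s1,
                "region_1": rc1.value,
                "sample_2": s2,
                "region_2": rc2.value,
            }
            res = tests.count(_chi2_row([row1, row2], config.yates_correction))
            row.update({f"{k}_overall": v for k, v in res.items()})
            cg_table = [
                [row1[2] + row1[3], row1[0] + row1[1]],
                [row2[2] + row2[3], row2[0] + row2[1]],
            ]
            res = tests.count(_chi2_row(cg_table, config.yates_correction))
            row["chi2_cg_to_at"] = res["chi2"]
            row["p_cg_to_at"] = res["p"]
            region_test_rows.append(row)
        write_tsv(pd.DataFrame(region_test_rows), out_dir / "region_tests.tsv")
        region_summary = {
            "n_alignments": len(alignments),
            "regions_with_codons": sorted(
                rc.value
                for rc in RegionClass
                if region_counts["hybrid"][rc].n_sc(code) > 0
            ),
        }

    # ---- stage 4: methylation-signature ratios per partition
    meth_partitions = ["all"]
    if assignments:
        meth_partitions += ["mapped", "introgressed", "non_introgressed"]
    meth_rows = []
    ttest_rows = []
    aa_pair_rows = []
    for label in meth_partitions:
        if label not in label_order:
            continue
        cc_r, bp_r = pooled["recipient"][label], pooled_bp["recipient"][label]
        cc_h, bp_h = pooled["hybrid"][label], pooled_bp["hybrid"][label]
        for name, table in signature_tables((cc_r, bp_r), (cc_h, bp_h), code).items():
            (num_r, den_r), (num_h, den_h) = table
            r_r = _ratio(num_r, den_r)
            r_h = _ratio(num_h, den_h)
            row = {
                "partition": label,
                "ratio": name,
                "num_recipient": num_r,
                "den_recipient": den_r,
                "ratio_recipient": r_r,
                "num_hybrid": num_h,
                "den_hybrid": den_h,
                "ratio_hybrid": r_h,
                "cross_ratio": _opt(
                    cross_sample_ratio(
                        None if np.isnan(r_h) else r_h,
                        None if np.isnan(r_r) else r_r,
                    )
                ),
            }
            row.update(tests.count(_chi2_row(table, config.yates_correction)))
            meth_rows.append(row)

        cross_by_aa = {}
        for aa in AG_PAIR_AMINO_ACIDS:
            families = ["primary"] + (["alt"] if aa in ALT_FAMILY else [])
            for family in families:
                pr = per_aa_ag_pair_counts(cc_r, aa, family=family, code=code)
                ph = per_aa_ag_pair_counts(cc_h, aa, family=family, code=code)
                r_r = _ratio(pr["n_A"], pr["n_G"])
                r_h = _ratio(ph["n_A"], ph["n_G"])
                cross = cross_sample_ratio(
                    None if np.isnan(r_h) else r_h,
                    None if np.isnan(r_r) else r_r,
                )
                if family == "primary":
                    cross_by_aa[aa] = cross
                row = {
                    "partition": label,
                    "amino_acid": aa,
                    "family": family,
                    "codon_A": pr["codon_A"],
                    "codon_G": pr["codon_G"],
                    "n_A_recipient": pr["n_A"],
                    "n_G_recipient": pr["n_G"],
                    "ratio_recipient": r_r,
                    "n_A_hybrid": ph["n_A"],
                    "n_G_hybrid": ph["n_G"],
                    "ratio_hybrid": r_h,
                    "cross_ratio": _opt(cross),
                }
                row.update(
                    tests.count(
                        _chi2_row(
                            [[pr["n_A"], pr["n_G"]], [ph["n_A"], ph["n_G"]]],
                            config.yates_correction,
                        )
                    )
                )
                aa_pair_rows.append(row)

        # CpG-context pair amino acids (4) vs the others (7), on cross ratios;
        # n = 4 vs 7 is tiny by construction and flagged in the summary.
        group_cpg = [
            cross_by_aa[aa]
            for aa in CPG_PAIR_AMINO_ACIDS
            if cross_by_aa.get(aa) is not None
        ]
        group_other = [
            cross_by_aa[aa]
            for aa in AG_PAIR_AMINO_ACIDS
            if aa not in CPG_PAIR_AMINO_ACIDS and cross_by_aa.get(aa) is not None
        ]
        if len(group_cpg) >= 2 and len(group_other) >= 2:
            res = two_sample_t_test(
                group_cpg, group_other, equal_var=config.equal_variance_t
            )
            tests.n += 1
            ttest_rows.append(
                {
                    "partition": label,
                    "n_cpg_group": len(group_cpg),
                    "n_other_group": len(group_other),
                    "t": res.statistic,
                    "df": res.df,
                    "p": res.p_value,
                }
            )
    write_tsv(pd.DataFrame(meth_rows), out_dir / "methylation_ratios.tsv")
    write_tsv(pd.DataFrame(aa_pair_rows), out_dir / "aa_pair_ratios.tsv")
    if ttest_rows:
        write_tsv(pd.DataFrame(ttest_rows), out_dir / "aa_pair_ttest.tsv")

    # ---- summary + manifest
    summary = {
        "seed": config.seed,
        "n_records": {"recipient": len(recipient), "hybrid": len(hybrid)},
        "n_sc": {
            "recipient": pooled["recipient"]["all"].n_sc(code),
            "hybrid": pooled["hybrid"]["all"].n_sc(code),
        },
        "n_invalid_codons": {
            "recipient": pooled["recipient"]["all"].n_invalid,
            "hybrid": pooled["hybrid"]["all"].n_invalid,
        },
        "partitions": label_order,
        "region_stage": region_summary or None,
        "cronbach_alpha": {
            f'{r["sample"]}:{r["scheme"]}': r["cronbach_alpha"] for r in alpha_rows
        },
        "aa_pair_ttest": ttest_rows,
        "n_statistical_tests": tests.n,
        "note_small_groups": "aa-pair t-test compares n=4 vs n=7 cross ratios",
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=2, default=float)

    config.to_yaml(out_dir / "config.yaml")
    manifest = {
        "scubshift_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
        "outputs": sorted(p.name for p in out_dir.iterdir() if p.is_file()),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
    return summary
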