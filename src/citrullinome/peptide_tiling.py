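"""Tiled-peptide (epitope-mapping) design and case/control ratio statistics.

A peptide array covers a protein with overlapping 12-mers tiled at single
amino-acid increments, in three forms: native, citrulline-substituted
(every arginine replaced) and homocitrulline-substituted (every lysine
replaced).  Citrulline and homocitrulline are encoded as single configurable
symbols outside the 20-letter alphabet ('X' and 'Z' by default); these
arrays are synthesized, not translated, so the symbols are literal.

Per-sample binding signals attach to a :class:`TileSet`; ``ratio_analysis``
computes case/control mean ratios per tile, isotype and variant, tests group
differences on the log scale, and correlates ratio profiles between isotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

from .proteome_core import bh_adjust

log = logging.getLogger(__name__)

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
DEFAULT_CIT = "X"
DEFAULT_HOMOCIT = "Z"


@dataclass
class TileSet:
    """Overlapping peptide tiles of one sequence, with optional signals.

    ``tiles`` columns: tile_id, start (1-based), variant
    (native/cit/homocit), peptide, modified (whether any substitution was
    made).  ``signals`` is tile_id × sample; ``sample_map`` maps sample →
    (group, isotype).
    """

    seq_id: str
    sequence: str
    window: int
    tiles: pd.DataFrame
    signals: pd.DataFrame | None = None
    sample_map: pd.DataFrame | None = None

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)

    def variant_tiles(self, variant: str) -> pd.DataFrame:
        return self.tiles[self.tiles["variant"] == variant]


def tile_id(seq_id: str, start: int, variant: str) -> str:
    return f"{seq_id}|{start}|{variant}"


def tile_sequence(
    seq_id: str,
    sequence: str,
    window: int = 12,
    step: int = 1,
    extra_symbols: str = "",
) -> TileSet:
    """Native tiles of ``sequence`` at starts 1..L−window+1 (1-based)."""
    sequence = sequence.upper()
    allowed = AA20 | set(extra_symbols.upper())
    bad = set(sequence) - allowed
    if bad:
        raise ValueError(f"sequence contains non-amino-acid symbols: {sorted(bad)}")
    rows = []
    if len(sequence) < window:
        log.warning("sequence length %d < window %d: empty tile set",
                    len(sequence), window)
    else:
        for start in range(1, len(sequence) - window + 2, step):
            pep = sequence[start - 1:start - 1 + window]
            rows.append({"tile_id": tile_id(seq_id, start, "native"),
                         "start": start, "variant": "native",
                         "peptide": pep, "modified": False})
    tiles = pd.DataFrame(rows, columns=["tile_id", "start", "variant",
                                        "peptide", "modified"])
    return TileSet(seq_id=seq_id, sequence=sequence, window=window, tiles=tiles)


def make_variants(
    ts: TileSet,
    cit_symbol: str = DEFAULT_CIT,
    homocit_symbol: str = DEFAULT_HOMOCIT,
) -> TileSet:
    """Add citrulline (R→cit) and homocitrulline (K→homocit) tile variants.

    Tiles without the target residue are emitted unchanged and flagged
    unmodified; positions are identical across variants.
    """
    for sym, target in ((cit_symbol, "R"), (homocit_symbol, "K")):
        if len(sym) != 1 or sym.upper() in AA20:
            raise ValueError(f"substitution symbol {sym!r} collides with the "
                             "standard amino-acid alphabet")
    native = ts.variant_tiles("native")
    rows = [native]
    for variant, target, sym in (("cit", "R", cit_symbol),
                                 ("homocit", "K", homocit_symbol)):
        v = native.copy()
        v["variant"] = variant
        v["modified"] = v["peptide"].str.contains(target)
        v["peptide"] = v["peptide"].str.replace(target, sym, regex=False)
        v["tile_id"] = [tile_id(ts.seq_id, s, variant) for s in v["start"]]
        rows.append(v)
    tiles = pd.concat(rows, ignore_index=True)
    return replace(ts, tiles=tiles)


# -- FASTA / TSV I/O --------------------------------------------------------

def write_tiles_fasta(ts: TileSet, path: str | Path,
                      cit_symbol: str = DEFAULT_CIT,
                      homocit_symbol: str = DEFAULT_HOMOCIT) -> None:
    mapping = f"cit={cit_symbol} homocit={homocit_symbol}"
    records = [
        SeqRecord(Seq(r.peptide), id=r.tile_id, description=mapping)
        for r in ts.tiles.itertuples()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_source_fasta(path: str | Path) -> tuple[str, str]:
    """Read the first record of a FASTA file as (id, sequence)."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    return rec.id, str(rec.seq).upper()


def write_signals_tsv(ts: TileSet, signals_path: str | Path,
                      sample_map_path: str | Path) -> None:
    if ts.signals is None or ts.sample_map is None:
        raise ValueError("tile set has no signals attached")
    out = ts.signals.copy()
    out.index.name = "tile_id"
    out.to_csv(signals_path, sep="\t")
    sm = ts.sample_map.copy()
    sm.index.name = "sample"
    sm.to_csv(sample_map_path, sep="\t")


def read_signals_tsv(ts: TileSet, signals_path: str | Path,
                     sample_map_path: str | Path) -> TileSet:
    signals = pd.read_csv(signals_path, sep="\t", index_col="tile_id")
    signals.index.name = None
    sm = pd.read_csv(sample_map_path, sep="\t", index_col="sample")
    sm.index.name = None
    return replace(ts, signals=signals, sample_map=sm)


# -- ratio statistics -------------------------------------------------------

@dataclass
class RatioResult:
    """Per tile × isotype ratio table plus isotype–isotype correlations.

    ``table`` columns: tile_id, start, variant, isotype, mean_case,
    mean_control, ratio, p, padj, undefined (zero control mean).
    ``isotype_corr`` maps variant → isotype × isotype Pearson r DataFrame.
    """

    table: pd.DataFrame
    isotype_corr: dict[str, pd.DataFrame]
    case_group: str
    control_group: str

    def top_tile(self, variant: str = "cit", isotype: str | None = None) -> pd.Series:
        sub = self.table[self.table["variant"] == variant]
        if isotype is not None:
            sub = sub[sub["isotype"] == isotype]
        sub = sub.dropna(subset=["ratio"])
        if sub.empty:
            raise ValueError("no defined ratios for this variant/isotype")
        return sub.loc[sub["ratio"].idxmax()]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _group_compare_log(groups: list[np.ndarray]) -> float:
    """Two-sided p for a difference in mean log signal (t-test or ANOVA)."""
    logs = [np.log(np.maximum(g, 1e-300)) for g in groups]
    if np.ptp(np.concatenate(logs)) == 0:
        return 1.0
    if len(logs) == 2:
        res = stats.ttest_ind(logs[0], logs[1], equal_var=True)
        p = float(res.pvalue)
    else:
        res = stats.f_oneway(*logs)
        p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def ratio_analysis(
    ts: TileSet,
    case_group: str | None = None,
    control_group: str = "control",
) -> RatioResult:
    """Case/control mean-signal ratios and tests per tile × variant × isotype.

    Ratios are on the raw (multiplicative) scale; the group comparison is a
    pooled t-test on log signals (one-way ANOVA when more than two groups are
    present), BH-adjusted across tiles within each variant × isotype stratum.
    Pearson correlations between isotype ratio vectors are reported per
    variant.
    """
    if ts.signals is None or ts.sample_map is None:
        raise ValueError("tile set has no signals attached")
    sm = ts.sample_map
    groups = list(dict.fromkeys(sm["group"]))
    if case_group is None:
        others = [g for g in groups if g != control_group]
        if len(others) != 1:
            raise ValueError("cannot infer case group; pass case_group explicitly")
        case_group = others[0]
    isotypes = list(dict.fromkeys(sm["isotype"]))
    meta = ts.tiles.set_index("tile_id")
    rows = []
    for iso in isotypes:
        iso_samples = sm.index[sm["isotype"] == iso]
        case_cols = [s for s in iso_samples if sm.loc[s, "group"] == case_group]
        ctrl_cols = [s for s in iso_samples if sm.loc[s, "group"] == control_group]
        if len(case_cols) < 2 or len(ctrl_cols) < 2:
            raise ValueError(f"isotype {iso}: need >= 2 samples per group")
        other_groups = [g for g in groups if g not in (case_group, control_group)]
        for tid in ts.signals.index:
            xc = ts.signals.loc[tid, case_cols].to_numpy(dtype=float)
            xt = ts.signals.loc[tid, ctrl_cols].to_numpy(dtype=float)
            mc, mt = float(xc.mean()), float(xt.mean())
            undefined = mt == 0.0
            ratio = np.nan if undefined else mc / mt
            if undefined:
                log.warning("tile %s (%s): zero control mean; ratio undefined", tid, iso)
            gvals = [xc, xt] + [
                ts.signals.loc[tid, [s for s in iso_samples
                                     if sm.loc[s, "group"] == g]].to_numpy(dtype=float)
                for g in other_groups
            ]
            p = _group_compare_log(gvals)
            rows.append({"tile_id": tid, "start": meta.loc[tid, "start"],
                         "variant": meta.loc[tid, "variant"], "isotype": iso,
                         "mean_case": mc, "mean_control": mt,
                         "ratio": ratio, "p": p, "undefined": undefined})
    table = pd.DataFrame(rows)
    table["padj"] = np.nan
    for (_, _), idx in table.groupby(["variant", "isotype"]).groups.items():
        table.loc[idx, "padj"] = bh_adjust(table.loc[idx, "p"].to_numpy())
    # isotype-isotype correlation of ratio vectors, per variant
    corr: dict[str, pd.DataFrame] = {}
    for variant in dict.fromkeys(table["variant"]):
        wide = (table[table["variant"] == variant]
                .pivot(index="start", columns="isotype", values="ratio")
                .dropna())
        if wide.shape[0] >= 3 and wide.shape[1] >= 1:
            corr[variant] = wide.corr(method="pearson")
    return RatioResult(table=table, isotype_corr=corr,
                       case_group=case_group, control_group=control_group)
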