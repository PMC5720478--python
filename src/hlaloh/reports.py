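"""TSV report writers with a fixed column order and 4-decimal floats."""

from __future__ import annotations

from pathlib import Path

from .pipeline import GeneResult

__all__ = ["write_report", "GENE_COLUMNS", "SITE_COLUMNS"]

GENE_COLUMNS = ["gene", "allele1", "allele2", "cn1", "cn2", "pval",
                "n_sites", "n_bins", "verdict"]
SITE_COLUMNS = ["gene", "pos1", "pos2", "base1", "base2", "baf",
                "tumor1", "tumor2", "germline1", "germline2"]


def _fmt(value: float | None) -> str:
    return "NA" if value is None else f"{value:.4f}"


def write_report(results: list[GeneResult], out_dir: str | Path) -> dict[str, Path]:
    """Write the gene-level and per-site TSVs; returns the file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gene_path = out_dir / "hla_loss_calls.tsv"
    site_path = out_dir / "hla_baf_sites.tsv"
    with open(gene_path, "w") as fh:
        fh.write("\t".join(GENE_COLUMNS) + "\n")
        for r in results:
            fh.write("\t".join([
                r.gene, r.allele1, r.allele2, _fmt(r.cn1), _fmt(r.cn2),
                _fmt(r.p_value), str(r.n_sites), str(r.n_bins), r.verdict,
            ]) + "\n")
    with open(site_path, "w") as fh:
        fh.write("\t".join(SITE_COLUMNS) + "\n")
        for r in results:
            for s in r.baf_sites:
                fh.write("\t".join([
                    r.gene, str(s.site.pos1), str(s.site.pos2),
                    s.site.base1, s.site.base2, _fmt(s.baf),
                    str(s.tumor1), str(s.tumor2),
                    str(s.germline1), str(s.germline2),
                ]) + "\n")
    return {"genes": gene_path, "sites": site_path}
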