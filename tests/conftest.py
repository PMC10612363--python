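import io

import pytest

from ystrkit.panels import (
    AlleleRange,
    LocusDefinition,
    LocusPanel,
    build_panel,
    parse_haplotype_table,
)


@pytest.fixture(scope="session")
def panel27():
    return build_panel("yfiler_plus_27")


@pytest.fixture(scope="session")
def panel23():
    return build_panel("single_copy_23")


def int_panel(n_loci: int, name: str = "toy") -> LocusPanel:
    """Small all-single-copy integer panel for simulator/network tests."""
    return LocusPanel(
        name,
        tuple(
            LocusDefinition(f"L{i + 1}", allele_range=AlleleRange(5.0, 60.0))
            for i in range(n_loci)
        ),
    )


def default_token(locus: LocusDefinition) -> str:
    mid = int((locus.allele_range.lo + locus.allele_range.hi) / 2)
    if locus.copy_number == 2:
        return f"{mid}-{mid}"
    return str(mid)


def table_text(panel: LocusPanel, rows: list[dict]) -> str:
    """Build a haplotype TSV: each row dict gives sample_id/population and
    optional per-marker token overrides; unspecified markers get a default."""
    header = ["sample_id", "population", "region", "haplogroup"]
    header += list(panel.marker_names)
    lines = ["\t".join(header)]
    for row in rows:
        cells = [
            row.get("sample_id", "S1"),
            row.get("population", "POP"),
            row.get("region", ""),
            row.get("haplogroup", ""),
        ]
        for locus in panel:
            cells.append(row.get(locus.name, default_token(locus)))
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def parse_text(text: str, panel: LocusPanel, **kw):
    return parse_haplotype_table(io.StringIO(text), panel, **kw)
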