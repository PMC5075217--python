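"""Target-panel definitions.

A panel is an ordered list of amplicons (BED-convention coordinates:
0-based, half-open) annotated with a gene and a CNV-site label.  Sites are
the exon-level units over which calls are reported; within a gene a site
must be a contiguous run of amplicons in coordinate order.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Amplicon", "AmpliconPanel", "PanelError", "load_panel", "write_panel"]


class PanelError(ValueError):
    """Malformed or inconsistent panel definition."""


@dataclass(frozen=True)
class Amplicon:
    id: str
    chrom: str
    start: int  # 0-based, half-open
    end: int
    gene: str
    site_id: str

    def __post_init__(self):
        if self.start >= self.end:
            raise PanelError(
                f"amplicon {self.id!r}: start ({self.start}) must be < end ({self.end})")
        if not self.gene or not self.site_id:
            raise PanelError(f"amplicon {self.id!r}: empty gene or site_id")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def length(self) -> int:
        return self.end - self.start


class AmpliconPanel:
    """Ordered, validated amplicon panel.

    Amplicons are stored sorted by (chrom, start, end); ids must be unique.
    ``sites`` maps each site_id to the list of its amplicon ids, in order.
    """

    def __init__(self, amplicons):
        amps = sorted(amplicons, key=lambda a: (a.chrom, a.start, a.end, a.id))
        if not amps:
            raise PanelError("panel is empty")
        seen = set()
        for a in amps:
            if a.id in seen:
                raise PanelError(f"duplicate amplicon id {a.id!r}")
            seen.add(a.id)
        self.amplicons: list[Amplicon] = amps
        self._index = {a.id: i for i, a in enumerate(amps)}
        sites: dict[str, list[str]] = {}
        site_gene: dict[str, str] = {}
        last_site = None
        closed = set()
        for a in amps:
            if a.site_id != last_site:
                if a.site_id in closed:
                    raise PanelError(
                        f"site {a.site_id!r} is not a contiguous run of amplicons")
                if last_site is not None:
                    closed.add(last_site)
                last_site = a.site_id
            if a.site_id in site_gene and site_gene[a.site_id] != a.gene:
                raise PanelError(
                    f"site {a.site_id!r} spans genes "
                    f"{site_gene[a.site_id]!r} and {a.gene!r}")
            site_gene[a.site_id] = a.gene
            sites.setdefault(a.site_id, []).append(a.id)
        self.sites: dict[str, list[str]] = sites
        self.site_gene: dict[str, str] = site_gene

    def __len__(self) -> int:
        return len(self.amplicons)

    def __iter__(self):
        return iter(self.amplicons)

    def __getitem__(self, amplicon_id: str) -> Amplicon:
        return self.amplicons[self._index[amplicon_id]]

    def index_of(self, amplicon_id: str) -> int:
        return self._index[amplicon_id]

    @property
    def ids(self) -> list[str]:
        return [a.id for a in self.amplicons]

    @property
    def genes(self) -> set[str]:
        return {a.gene for a in self.amplicons}

    @property
    def chroms(self) -> set[str]:
        return {a.chrom for a in self.amplicons}

    def gene_of(self, amplicon_id: str) -> str:
        return self[amplicon_id].gene

    def site_of(self, amplicon_id: str) -> str:
        return self[amplicon_id].site_id

    def amplicons_of_gene(self, gene: str) -> list[str]:
        return [a.id for a in self.amplicons if a.gene == gene]

    def distance(self, id_a: str, id_b: str) -> float:
        """Genomic distance between amplicon midpoints; +inf across chroms."""
        a, b = self[id_a], self[id_b]
        if a.chrom != b.chrom:
            return float("inf")
        return abs(a.midpoint - b.midpoint)


def load_panel(path) -> AmpliconPanel:
    """Read a 6-column tab-separated BED-like panel file
    (chrom, start, end, id, gene, site_id)."""
    amplicons = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise PanelError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, "
                    f"got {len(fields)}")
            chrom, start_s, end_s, amp_id, gene, site_id = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise PanelError(
                    f"{path}:{lineno}: non-integer coordinate") from exc
            try:
                amplicons.append(Amplicon(amp_id, chrom, start, end, gene, site_id))
            except PanelError as exc:
                raise PanelError(f"{path}:{lineno}: {exc}") from exc
    return AmpliconPanel(amplicons)


def write_panel(panel: AmpliconPanel, path) -> None:
    with open(path, "w") as fh:
        for a in panel.amplicons:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.id}\t{a.gene}\t{a.site_id}\n")
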