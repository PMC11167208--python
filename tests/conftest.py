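import io

import pytest

from bbikit import write_bigbed, write_bigwig
from bbikit.fixtures import GenSpec, gen_bed, gen_bedgraph, gen_chrom_sizes


def make_bigwig(tmp_path, spec: GenSpec, name="t.bw", opts=None, chrom_sizes=None):
    cs = chrom_sizes or gen_chrom_sizes(spec)
    items = gen_bedgraph(spec, cs)
    path = tmp_path / name
    report = write_bigwig(iter(items), cs, str(path), opts)
    return path, cs, items, report


def make_bigbed(tmp_path, spec: GenSpec, name="t.bb", opts=None, chrom_sizes=None,
                **kw):
    cs = chrom_sizes or gen_chrom_sizes(spec)
    items = gen_bed(spec, cs)
    path = tmp_path / name
    report = write_bigbed(iter(items), cs, str(path), opts, **kw)
    return path, cs, items, report


def bigwig_bytes(items, cs, opts=None) -> bytes:
    buf = io.BytesIO()
    write_bigwig(iter(items), cs, buf, opts)
    return buf.getvalue()


@pytest.fixture
def small_wig(tmp_path):
    spec = GenSpec(seed=42, n_chroms=3, chrom_len_range=(20_000, 60_000),
                   n_items=800)
    path, cs, items, report = make_bigwig(tmp_path, spec)
    return {"path": path, "chrom_sizes": cs, "items": items,
            "report": report, "spec": spec}


@pytest.fixture
def small_bed(tmp_path):
    spec = GenSpec(seed=43, n_chroms=3, chrom_len_range=(20_000, 60_000),
                   n_items=600, overlap_allowed=True)
    path, cs, items, report = make_bigbed(tmp_path, spec, bed_type="bed6")
    return {"path": path, "chrom_sizes": cs, "items": items,
            "report": report, "spec": spec}
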