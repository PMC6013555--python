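"""Shared fixtures: reference cross-age records and small reusable objects."""

from __future__ import annotations

import pytest

from npscreen import reference
from npscreen.annotation import DisorderPool
from npscreen.deg import DEGRecord


def cross_age_reference_records(
    disorder: str,
) -> tuple[dict[str, tuple[list[DEGRecord], list[DEGRecord]]], DisorderPool]:
    """Gene-level DEG records per region/age from the bundled cross-age table.

    Fold changes and significance flags come from the published table; the
    p-values are placeholders consistent with the flags (the table prints
    significance markers, not p-values).
    """
    entries = [e for e in reference.CROSS_AGE_TABLE if e.disorder == disorder]
    genes = {e.gene for e in entries}
    # Pad the pool with inert symbols so it is a superset of the table genes.
    pool = DisorderPool(
        disorder=disorder,
        term_sets={"GO:0000001": genes | {f"PAD{i}" for i in range(5)}},
    )
    per_region: dict[str, tuple[list[DEGRecord], list[DEGRecord]]] = {}
    for region in ("cortex", "hippocampus"):
        recs7, recs18 = [], []
        for e in entries:
            if e.region != region:
                continue
            for age, fc, sig, bucket in (
                (7, e.fc[0], e.significant[0], recs7),
                (18, e.fc[1], e.significant[1], recs18),
            ):
                bucket.append(
                    DEGRecord(
                        gene=e.gene,
                        condition=(region, age),
                        p_value=0.01 if sig else 0.5,
                        fold_change=fc,
                        significant=sig,
                        representative_probe="100000_at",
                    )
                )
        per_region[region] = (recs7, recs18)
    return per_region, pool


@pytest.fixture(scope="session")
def paper_term_ids() -> list[str]:
    return sorted(reference.TERM_SIZES)
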