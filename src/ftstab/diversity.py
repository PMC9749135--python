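"""Shannon–Wiener diversity (natural log) per sample."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import AbundanceTable, TableValidationError


def shannon(table: AbundanceTable) -> pd.DataFrame:
    """Shannon–Wiener index H' = -sum p_i ln p_i and richness per sample.

    Counts, copies and relative tables are all accepted; rows are
    normalized internally.  H' is reported in nats, so 0 <= H' <= ln(richness).
    """
    values = table.values
    sums = values.sum(axis=1)
    if (sums <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, sums) if t <= 0]
        raise TableValidationError(f"zero-sum samples have undefined diversity: {bad}")
    p = values / sums[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=1)
    richness = (values > 0).sum(axis=1)
    return pd.DataFrame(
        {"sample_id": table.sample_ids, "H": h, "richness": richness,
         "domain": table.domain},
    ).set_index("sample_id", drop=False)
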