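import numpy as np
import pandas as pd

from heistrl.task import TRIAL_COLUMNS


def manual_trials(rows, subject=0):
    """Build a TrialTable from compact per-trial dicts with sensible defaults."""
    out = []
    for i, r in enumerate(rows):
        rec = dict(
            subject=subject,
            session=0,
            block=0,
            condition="dependent",
            context=1,
            trial_index=i,
            trial_type="forced",
            valence="gain",
            door_presented="dark",
            choice=pd.NA,
            state=pd.NA,
            outcome=np.nan,
            p_true=0.8,
        )
        rec.update(r)
        if rec["choice"] is not pd.NA and rec["state"] is not pd.NA and np.isnan(rec["outcome"]):
            if rec["state"] == "heist":
                rec["outcome"] = 1 if rec["valence"] == "gain" else -1
            else:
                rec["outcome"] = 0
        out.append(rec)
    return pd.DataFrame(out, columns=TRIAL_COLUMNS)
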