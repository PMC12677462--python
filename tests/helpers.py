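import pandas as pd

from ruralscale.geodata import ZipUniverse


def make_universe(rows):
    """Build a ZipUniverse from (zip5, population, is_rural) tuples."""
    df = pd.DataFrame(rows, columns=["zip5", "population", "is_rural"])
    return ZipUniverse(records=df)
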