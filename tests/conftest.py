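import pytest
from hypothesis import settings

from pescreen.library_io import EditSpec, PairDesign, apply_edit
from pescreen.synthetic import LibraryDesignConfig, design_library, revcomp

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_toy_pair(edit_kind: str = "substitution") -> PairDesign:
    """Hand-assembled 47-nt pair with the nick at wide-target index 21."""
    spacer = "GTCACCTCCAATGACTAGGG"
    wide = "AACC" + spacer + "TGG" + "ACGTACGTACGTACGTACGT"
    nick = 4 + 17
    if edit_kind == "substitution":
        edit = EditSpec(kind="substitution", offset_from_nick=1, payload="T")
    elif edit_kind == "insertion":
        edit = EditSpec(kind="insertion", offset_from_nick=0, payload="AT")
    else:
        edit = EditSpec(kind="deletion", offset_from_nick=0, payload=wide[nick:nick + 2])
    edited = apply_edit(wide, nick, edit)
    return PairDesign(
        pair_id=f"toy_{edit_kind}",
        spacer=spacer,
        pbs=revcomp(wide[nick - 13:nick]),
        rt_template=revcomp(edited[nick:nick + 13]),
        barcode="ACGTACGTACGTACGTAC",
        upstream4="TTCA",
        wide_target=wide,
        edited_wide_target=edited,
        edit=edit,
    ).validate()


def make_read(pair: PairDesign, region: str | None = None) -> str:
    """Amplicon read for a pair: anchors, region, key, tail."""
    region = pair.edited_wide_target if region is None else region
    return (pair.flank5 + region + pair.flank3 + pair.upstream4
            + pair.barcode + "AGCTTGGCGT")


@pytest.fixture
def toy_pair() -> PairDesign:
    return make_toy_pair()


@pytest.fixture(scope="session")
def small_library():
    """24 base pegRNAs + PAM-silent variants, one barcode each."""
    cfg = LibraryDesignConfig(n_base_pegrnas=24, pam_silent_fraction=0.25,
                              barcodes_per_pegrna=1, seed=42)
    return design_library(cfg)
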