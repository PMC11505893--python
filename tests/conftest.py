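import pytest

import fmofrag as ff


@pytest.fixture(scope="session")
def ala3():
    return ff.build_polypeptide("AAA")


@pytest.fixture(scope="session")
def kae():
    return ff.build_polypeptide("KAE")


@pytest.fixture(scope="session")
def zn_peptide():
    """Zn-centred cyclic 24-mer with D-residues, AIB and four His."""
    return ff.build_zn_cyclic_peptide()


@pytest.fixture(scope="session")
def zn_atom(zn_peptide):
    return next(a for a in zn_peptide.atoms if a.element == "ZN")


@pytest.fixture(scope="session")
def zn_auto(zn_peptide):
    return ff.auto_fragment(zn_peptide)


@pytest.fixture(scope="session")
def ligand_complex():
    """(structure, named serial map) for the covalent-ligand system."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ff.build_covalent_ligand_complex()


@pytest.fixture(scope="session")
def ligand_auto(ligand_complex):
    import warnings
    st, _ = ligand_complex
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ff.auto_fragment(st)


@pytest.fixture(scope="session")
def toy_result(kae):
    frag = ff.auto_fragment(kae)
    return ff.make_toy_result(frag, seed=11)
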