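"""Shared fixtures: tiny hand-written contig tables and a reusable simulation."""

import textwrap

import pytest

from dualtcr import SimConfig, build_cell_profiles, simulate_repertoire


@pytest.fixture
def tenx_csv(tmp_path):
    """Four-contig 10x file: TRA, TRB, an IGH to drop, and a second TRA.

    Covers the dialect's productive vocabulary ("True"/"None"/"False").
    """
    content = textwrap.dedent(
        """\
        barcode,is_cell,contig_id,high_confidence,chain,v_gene,d_gene,j_gene,c_gene,full_length,productive,cdr3,cdr3_nt,reads,umis
        AAAC-1,True,AAAC-1_contig_1,True,TRA,TRAV1-2,None,TRAJ33,TRAC,True,True,CAVMDSNYQLIW,TGTGCCGTGATGGATAGCAACTATCAGTTAATCTGG,1200,12
        AAAC-1,True,AAAC-1_contig_2,True,TRB,TRBV6-4,TRBD1,TRBJ2-2,TRBC2,True,True,CASSDTGELFF,TGTGCCAGCAGTGACACCGGGGAGCTGTTTTTT,3400,30
        AAAC-1,True,AAAC-1_contig_3,True,IGH,IGHV1-2,None,IGHJ4,IGHM,True,True,CARDY,TGTGCCAGAGATTAC,90,2
        AAAG-1,True,AAAG-1_contig_1,True,TRA,TRAV8-6*01,None,TRAJ9,TRAC,True,None,CAVSGGGADGLTF,TGTGCCGTGAGCGGAGGTGGCGCAGATGGACTCACCTTT,800,7
        """
    )
    path = tmp_path / "filtered_contig_annotations.csv"
    path.write_text(content)
    return path


@pytest.fixture
def airr_tsv(tmp_path):
    """Two-cell AIRR Rearrangement TSV with four rearrangements."""
    content = textwrap.dedent(
        """\
        sequence_id\tcell_id\tlocus\tv_call\tj_call\tjunction\tjunction_aa\tproductive\tduplicate_count
        seq1\tcellA\tTRA\tTRAV1-2*01\tTRAJ33*01\tTGTGCCGTGATGGATAGCAACTATCAGTTAATCTGG\tCAVMDSNYQLIW\tT\t12
        seq2\tcellA\tTRB\tTRBV6-4*02\tTRBJ2-2*01\tTGTGCCAGCAGTGACACCGGGGAGCTGTTTTTT\tCASSDTGELFF\tT\t30
        seq3\tcellB\tTRA\tTRAV8-6*01\tTRAJ9*01\tTGTGCCGTGAGCGGAGGTGGCGCAGATGGACTCACCTTT\tCAVSGGGADGLTF\tT\t7
        seq4\tcellB\tTRB\tTRBV21-1*01\tTRBJ1-1*01\tTGTGCCAGCAGCTTGGAA\tCASSLE\tF\t3
        """
    )
    path = tmp_path / "rearrangements.airr.tsv"
    path.write_text(content)
    return path


@pytest.fixture
def metadata_csv(tmp_path):
    content = textwrap.dedent(
        """\
        barcode,patient_id,tissue,subset,cluster
        AAAC-1,patient01,T,CD8,terminal Tex
        cellA,patient01,P,CD4,naive
        cellB,patient02,N,CD8,ZNF683+CXCR6+ Trm
        """
    )
    path = tmp_path / "metadata.csv"
    path.write_text(content)
    return path


@pytest.fixture(scope="session")
def small_sim():
    """A 3,000-cell default-rate repertoire shared across tests."""
    table, truth = simulate_repertoire(SimConfig(n_cells=3000, seed=11))
    return table, truth


@pytest.fixture(scope="session")
def small_profiles(small_sim):
    table, _ = small_sim
    return build_cell_profiles(table)
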