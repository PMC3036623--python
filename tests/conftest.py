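"""Shared fixtures: toy MSA builders and a minimal BLAST XML writer."""

from __future__ import annotations

import textwrap

import numpy as np
import pytest

from boundscan import AlignedHit, AnchoredMSA, QueryProtein, SimConfig, simulate_dataset


def make_msa(query_seq: str, rows: list[str], e_values: list[float] | None = None,
             query_id: str = "q") -> AnchoredMSA:
    """Build an AnchoredMSA from literal gapped row strings."""
    if e_values is None:
        e_values = [10.0 ** (-20 + i) for i in range(len(rows))]
    hits = [
        AlignedHit(f"h{i}", e, row) for i, (row, e) in enumerate(zip(rows, e_values))
    ]
    return AnchoredMSA(QueryProtein(query_id, query_seq), hits)


def random_query(rng: np.random.Generator, length: int, qid: str = "q") -> QueryProtein:
    return QueryProtein(qid, "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), length)))


def blast_xml(query_id: str, query_len: int, iterations: list[list[dict]]) -> str:
    """Render a minimal NCBI BLAST XML (outfmt 5) report.

    ``iterations`` is a list of rounds; each round is a list of hit
    dicts with keys: hit_id, and hsps = list of dicts with e_value,
    query_start, query_end, hit_start, hit_end, qseq, hseq.
    """
    iter_blocks = []
    for it_num, hits in enumerate(iterations, start=1):
        hit_blocks = []
        for hnum, hit in enumerate(hits, start=1):
            hsp_blocks = []
            for snum, hsp in enumerate(hit["hsps"], start=1):
                alen = len(hsp["qseq"])
                hsp_blocks.append(f"""
      <Hsp>
        <Hsp_num>{snum}</Hsp_num>
        <Hsp_bit-score>50.0</Hsp_bit-score>
        <Hsp_score>120</Hsp_score>
        <Hsp_evalue>{hsp["e_value"]}</Hsp_evalue>
        <Hsp_query-from>{hsp["query_start"]}</Hsp_query-from>
        <Hsp_query-to>{hsp["query_end"]}</Hsp_query-to>
        <Hsp_hit-from>{hsp["hit_start"]}</Hsp_hit-from>
        <Hsp_hit-to>{hsp["hit_end"]}</Hsp_hit-to>
        <Hsp_identity>{alen}</Hsp_identity>
        <Hsp_positive>{alen}</Hsp_positive>
        <Hsp_align-len>{alen}</Hsp_align-len>
        <Hsp_qseq>{hsp["qseq"]}</Hsp_qseq>
        <Hsp_hseq>{hsp["hseq"]}</Hsp_hseq>
        <Hsp_midline>{"+" * alen}</Hsp_midline>
      </Hsp>""")
            hit_blocks.append(f"""
    <Hit>
      <Hit_num>{hnum}</Hit_num>
      <Hit_id>{hit["hit_id"]}</Hit_id>
      <Hit_def>{hit["hit_id"]}</Hit_def>
      <Hit_accession>{hit["hit_id"]}</Hit_accession>
      <Hit_len>500</Hit_len>
      <Hit_hsps>{"".join(hsp_blocks)}
      </Hit_hsps>
    </Hit>""")
        iter_blocks.append(f"""
  <Iteration>
    <Iteration_iter-num>{it_num}</Iteration_iter-num>
    <Iteration_query-ID>{query_id}</Iteration_query-ID>
    <Iteration_query-def>{query_id}</Iteration_query-def>
    <Iteration_query-len>{query_len}</Iteration_query-len>
    <Iteration_hits>{"".join(hit_blocks)}
    </Iteration_hits>
    <Iteration_stat>
      <Statistics>
        <Statistics_db-num>1</Statistics_db-num>
        <Statistics_db-len>500</Statistics_db-len>
        <Statistics_hsp-len>0</Statistics_hsp-len>
        <Statistics_eff-space>0</Statistics_eff-space>
        <Statistics_kappa>0.041</Statistics_kappa>
        <Statistics_lambda>0.267</Statistics_lambda>
        <Statistics_entropy>0.14</Statistics_entropy>
      </Statistics>
    </Iteration_stat>
  </Iteration>""")
    return textwrap.dedent(f"""\
<?xml version="1.0"?>
<!DOCTYPE BlastOutput PUBLIC "-//NCBI//NCBI BlastOutput/EN" "http://www.ncbi.nlm.nih.gov/dtd/NCBI_BlastOutput.dtd">
<BlastOutput>
  <BlastOutput_program>psiblast</BlastOutput_program>
  <BlastOutput_version>PSIBLAST 2.13.0+</BlastOutput_version>
  <BlastOutput_reference>ref</BlastOutput_reference>
  <BlastOutput_db>nr</BlastOutput_db>
  <BlastOutput_query-ID>{query_id}</BlastOutput_query-ID>
  <BlastOutput_query-def>{query_id}</BlastOutput_query-def>
  <BlastOutput_query-len>{query_len}</BlastOutput_query-len>
  <BlastOutput_param>
    <Parameters>
      <Parameters_expect>0.001</Parameters_expect>
      <Parameters_gap-open>11</Parameters_gap-open>
      <Parameters_gap-extend>1</Parameters_gap-extend>
      <Parameters_filter>F</Parameters_filter>
    </Parameters>
  </BlastOutput_param>
  <BlastOutput_iterations>{"".join(iter_blocks)}
  </BlastOutput_iterations>
</BlastOutput>
""")


@pytest.fixture(scope="session")
def small_dataset():
    """30 simulated chains at the easy preset, shared across tests."""
    chains, manifest = simulate_dataset(SimConfig(n_chains=30, seed=11))
    return chains, manifest


def to_chain_data(chains):
    """Run extraction + labelling + encoding, yielding crossval inputs."""
    from boundscan import SignalParams, encode_dataset, extract_signals, label_sites
    from boundscan.classify import encode_labels
    from boundscan.evaluate import ChainData

    params = SignalParams()
    out = []
    for c in chains:
        sites = extract_signals(c.msa, params)
        labels = label_sites(sites, c.truth, params)
        X, _, positions = encode_dataset([(c.query.id, c.msa, sites, c.ann)])
        out.append(
            ChainData(c.query.id, X, encode_labels(labels), positions, sites, c.truth)
        )
    return out
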