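"""Packaged epitope tables for the two major shrimp pan-allergens.

The tables list experimentally mapped IgE-binding epitopes of shrimp
tropomyosin (TM) and arginine kinase (AK) that are conserved across all
four invertebrate groups analysed, together with the published per-group
presentation percentages (fraction of species in each group carrying a
conserved variant of the epitope). The tables are transcribed verbatim,
including the TM record spanning 241-260 whose printed placement is
internally inconsistent with the overlapping records around it; the
package surfaces that conflict (see ``consistency_check``) rather than
correcting printed data.

Columns: epitope_id, allergen, peptide, start, end, crustacean,
cockroach, mite, mollusc (presentation percentages).
"""

TABLE1_TM = """\
epitope_id\tallergen\tpeptide\tstart\tend\tcrustacean\tcockroach\tmite\tmollusc
tm01\tTM\tMDAIKKKMQAMKLEK\t1\t15\t100\t100\t100\t77
tm02\tTM\tIKKKMQAMKLEKDNA\t4\t18\t100\t100\t100\t10
tm03\tTM\tVAALNRRIQLLEEDL\t85\t99\t100\t100\t100\t3
tm04\tTM\tLNRRIQLLEEDLERS\t88\t102\t100\t100\t100\t33
tm05\tTM\tNRRIQLLEEDLERSEER\t89\t105\t100\t100\t100\t33
tm06\tTM\tRIQLLEEDLER\t91\t101\t100\t100\t100\t43
tm07\tTM\tRIQLLEEDLERSEER\t91\t105\t100\t100\t100\t33
tm08\tTM\tEASQAADESERMRK\t115\t128\t100\t100\t100\t50
tm09\tTM\tEASQAADESERMRKV\t115\t129\t100\t100\t78\t50
tm10\tTM\tLENQLKEA\t144\t151\t100\t100\t100\t37
tm11\tTM\tLAEEADRKYDEVARK\t154\t168\t100\t100\t100\t10
tm12\tTM\tEADRKYDEVARKLAM\t157\t171\t100\t100\t100\t10
tm13\tTM\tESKIVELEEELRVVG\t187\t201\t100\t100\t100\t17
tm14\tTM\tIVELEEELRVVGNNL\t190\t204\t100\t100\t100\t20
tm15\tTM\tLEEELRVVGNNLKSL\t193\t207\t100\t100\t100\t50
tm16\tTM\tKEVDRLEDELVNEKEKYKSI\t241\t260\t100\t100\t100\t60
tm17\tTM\tERSVQKLQKEVDRLEDE\t243\t259\t100\t100\t100\t90
tm18\tTM\tQKLQKEVDRLEDELV\t247\t261\t100\t100\t100\t93
tm19\tTM\tLQKEVDRLEDELV\t249\t261\t100\t100\t100\t100
tm20\tTM\tQKEVDRLEDELVNEK\t250\t264\t100\t100\t100\t93
tm21\tTM\tKEVDRLEDE\t251\t259\t100\t100\t100\t100
tm22\tTM\tVDRLEDELVNEKEKY\t253\t267\t100\t100\t100\t63
"""

TABLE2_AK = """\
epitope_id\tallergen\tpeptide\tstart\tend\tcrustacean\tcockroach\tmite\tmollusc
ak01\tAK\tSLLKKYLTKEVFDKL\t25\t39\t57\t100\t33\t9
ak02\tAK\tEGGIYDISNKRRMGL\t319\t333\t100\t100\t67\t36
ak03\tAK\tIYDISNKRRMGLTEF\t322\t336\t100\t100\t67\t55
ak04\tAK\tISNKRRMGLTEFQAV\t325\t339\t100\t100\t100\t45
ak05\tAK\tKRRMGLTEFQAVKEM\t328\t342\t100\t50\t100\t27
"""

FIXTURES = {"table1_tm": TABLE1_TM, "table2_ak": TABLE2_AK}
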