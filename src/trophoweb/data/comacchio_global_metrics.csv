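metric,PRE,POST
Number of nodes (N),23,23
Number of links (L),55,52
Network density (D),0.217,0.221
Weighted overall graph clustering coefficient (CL),0.174,0.142
Average distance (d),2.146,2.217
Small world index (CL/d),0.081,0.064
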