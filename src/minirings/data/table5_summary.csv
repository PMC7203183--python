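organism,domain,method,n,min_rh,min_cognates,pct_negative,significant,max_rh,max_cognates
Thermus thermophilus,Archaea,phyl,38,-46.1,G,62.6,True,44.2,Sec
Thermus thermophilus,Archaea,stru,48,-40.7,CDEM,67.9,True,38.7,G
Sulfolobus solfataricus,Archaea,phyl,44,-54.7,AKQSW,86.9,True,37.4,G
Sulfolobus solfataricus,Archaea,stru,46,-50.9,AGLNPQS,54.0,True,51.2,Sec
Escherichia coli,Bacteria,phyl,42,-37.4,G,64.7,True,35.6,Sec
Escherichia coli,Bacteria,stru,48,-35.6,ALNPQS,64.2,True,35.0,Sec
Streptomyces coelicolor,Bacteria,phyl,39,-46.8,A,90.9,True,30.7,R
Streptomyces coelicolor,Bacteria,stru,48,-32.9,GLT,72.0,True,32.3,G
Homo sapiens,Eukaryota,phyl,43,-36.0,"N,R",53.5,False,32.3,Sec
Homo sapiens,Eukaryota,stru,48,-25.5,AKQSW,80.4,True,19.1,G
Saccharomyces cerevisiae,Eukaryota,phyl,43,-36.1,S,79.1,True,27.5,Sec
Saccharomyces cerevisiae,Eukaryota,stru,48,-36.0,GT,53.6,False,34.9,Sec
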