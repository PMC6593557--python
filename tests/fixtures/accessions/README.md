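# Deposited-record fixtures

The accession-validation test (`tests/test_acceptance.py::TestDepositedRecords`)
checks the pipeline against the deposited GenBank records for the
*P. perniciosus* / *P. papatasi* sex-determination genes. The records are
not redistributed with this repository; fetch them once into this
directory as plain single-record FASTA files named `<ACCESSION>.fasta`:

    for acc in MK286443 MK286446 MK286453 MK286455 MK286466; do
      curl -s "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=${acc}&rettype=fasta&retmode=text" \
        > ${acc}.fasta
    done

Without these files the test fails at fixture load; every other test in
the suite is self-contained.
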