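<?xml version="1.0" encoding="UTF-8"?>
<drugbank>
  <drug>
    <drugbank-id>DB00001</drugbank-id>
    <targets>
      <target>
        <known-action>yes</known-action>
        <organism>Humans</organism>
        <polypeptide>
          <gene-name>GENA</gene-name>
          <external-identifiers>
            <external-identifier>
              <resource>UniProtKB</resource>
              <identifier>P10001</identifier>
            </external-identifier>
          </external-identifiers>
        </polypeptide>
      </target>
      <target>
        <known-action>unknown</known-action>
        <organism>Humans</organism>
        <polypeptide>
          <gene-name>GENB</gene-name>
          <external-identifiers>
            <external-identifier>
              <resource>UniProtKB</resource>
              <identifier>P10002</identifier>
            </external-identifier>
          </external-identifiers>
        </polypeptide>
      </target>
    </targets>
  </drug>
</drugbank>
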